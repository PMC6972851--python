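"""Classify county values for mapping with natural breaks.

Classifies final-year per-hectare toxic load (plain Jenks) and the log10
fold-change of oral load per hectare (zero-centered variant, so increases
and decreases never share a class).  The emitted county->class tables are
ready to join to county geometries by the county id.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from beetox import (compute_toxic_load, county_components, default_scenario,
                    fill_missing_series, generate_scenario, impute_census,
                    jenks_breaks, standardize_and_filter, zero_centered_breaks)
from beetox.consensus import consensus_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--k", type=int, default=5)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

out = args.out / "07_classify"
out.mkdir(parents=True, exist_ok=True)

cfg = default_scenario(seed=args.seed)
data = generate_scenario(cfg)
clean = standardize_and_filter(data.toxicity)
consensus = consensus_table(clean, [c.compound_id for c in cfg.compounds],
                            {c.compound_id: c.moa_group for c in cfg.compounds})
loads = fill_missing_series(compute_toxic_load(data.use, consensus),
                            cfg.year_list, fips_universe=data.counties["fips"])
comps = county_components(loads, impute_census(data.landuse), cfg.census_years)
y0, y1 = min(cfg.census_years), max(cfg.census_years)
final = comps[comps["year"] == y1]

frames = []
for route in ("contact", "oral"):
    vals = final[f"load_per_ha_{route}"].to_numpy()
    ok = np.isfinite(vals)
    res = jenks_breaks(vals[ok], args.k)
    frames.append(pd.DataFrame({"fips": final.loc[ok, "fips"],
                                "measure": f"{route}_load_per_ha_{y1}",
                                "value": vals[ok], "class": res.assignment}))
    print(f"{route} load/ha {y1}: k={args.k}, gvf={res.gvf:.3f}, "
          f"breaks={[f'{b:.3g}' for b in res.breaks]}")

wide = comps.pivot_table(index="fips", columns="year", values="load_per_ha_oral")
both = wide[(wide[y0] > 0) & (wide[y1] > 0)]
logfold = np.log10(both[y1] / both[y0])
res = zero_centered_breaks(logfold.to_numpy(), args.k)
frames.append(pd.DataFrame({"fips": both.index, "measure": "log10_oral_fold",
                            "value": logfold.to_numpy(), "class": res.assignment}))
print(f"oral fold-change map: zero-centered k={res.k}, gvf={res.gvf:.3f}, "
      f"zero boundary at class edge {res.breaks.index(0.0)}")

pd.concat(frames, ignore_index=True).to_csv(out / "county_classes.csv", index=False)
print(f"county->class table written to {out / 'county_classes.csv'}")
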