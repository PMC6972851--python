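"""Standardize toxicity records and select consensus contact/oral LD50s.

Applies the four acute-test criteria (<=4 days, contact/oral, adult bees,
positive value in ug/bee) and the six-tier consensus ladder, and reports how
often each tier was used -- the fallback tiers should be rare.
"""

import argparse
from pathlib import Path

from beetox import (default_scenario, generate_scenario,
                    standardize_and_filter)
from beetox.consensus import consensus_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

out = args.out / "02_consensus"
out.mkdir(parents=True, exist_ok=True)

cfg = default_scenario(seed=args.seed)
data = generate_scenario(cfg)
clean = standardize_and_filter(data.toxicity)
catalog = [c.compound_id for c in cfg.compounds]
moa = {c.compound_id: c.moa_group for c in cfg.compounds}
consensus = consensus_table(clean, catalog, moa)
consensus.to_csv(out / "consensus_ld50.csv", index=False)

print(f"{len(data.toxicity)} raw records -> {len(clean)} usable after filtering")
print(f"consensus rows: {len(consensus)} "
      f"({consensus['compound'].nunique()} compounds x 2 routes)")
print("tier usage (1=regulatory points ... 6=global median):")
print(consensus["tier"].value_counts().sort_index().to_string())
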