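"""Generator for the three synthetic source tables plus planted ground truth.

Emits, for a :class:`~beetox.scenario.ScenarioConfig`:

- a pesticide-use table (county x year x compound, kg_low/kg_high) in the
  style of the USGS county pesticide estimates, with a configurable
  fraction of county-years entirely absent;
- a census land-use table (county x census year: land, cropland, treated
  hectares) with withheld cells marked missing;
- a raw honey-bee toxicity table in the style of ECOTOX/PPDB extracts,
  mixing regulatory and other sources, point and unbounded estimates,
  ug/bee and mg/bee units, long-duration and larval tests;
- a :class:`GroundTruth` holding the pre-missingness county load series and
  the planted regional/national fold-changes, for parameter-recovery tests.

The intent (kg applied per county-year-compound before any missingness) is
deterministic given the config, so identical configs yield byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loads import KG_TO_UG
from .scenario import REGIONS, CompoundSpec, ScenarioConfig, ScenarioError

__all__ = ["GroundTruth", "SyntheticData", "generate_scenario",
           "generate_use_table", "generate_landuse_table",
           "generate_toxicity_records"]


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities, computed from the pre-missingness intent."""

    #: {"contact": fold, "oral": fold} of national toxic load, end/start year
    national_folds: dict
    #: per-region fold-changes (region, contact_fold, oral_fold)
    regional_folds: pd.DataFrame
    #: pre-missingness county-year loads (fips, year, kg_total, contact_load, oral_load)
    county_loads: pd.DataFrame
    #: calibrated generator parameters {"op_ratio": x, "neo_scale": alpha}
    calibration: dict


@dataclass(frozen=True)
class SyntheticData:
    counties: pd.DataFrame  # fips, region, urban, seed_excluded, land/cropland
    use: pd.DataFrame
    landuse: pd.DataFrame
    toxicity: pd.DataFrame
    truth: GroundTruth


def _counties(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_counties
    fips = [f"{i + 1:05d}" for i in range(n)]
    region = [config.region_of(i) for i in range(n)]
    urban = np.zeros(n, dtype=bool)
    if config.n_urban:
        urban[-config.n_urban:] = True

    cropland_base = rng.lognormal(mean=np.log(1.2e5), sigma=0.5, size=n)
    cropland_frac = rng.uniform(0.2, 0.7, size=n)
    treated_scale = rng.uniform(0.85, 1.15, size=n)
    land = cropland_base / cropland_frac
    # urban counties: negligible cropland, no insecticide use
    cropland_base[urban] = rng.uniform(200, 1000, size=urban.sum())
    land[urban] = rng.uniform(2e4, 8e4, size=urban.sum())

    df = pd.DataFrame({
        "fips": fips, "region": region, "urban": urban,
        "land_ha": land, "cropland_base_ha": cropland_base,
        "treated_scale": treated_scale,
    })
    df["seed_excluded"] = False
    if config.n_ca_like:
        ca_idx = df.index[(df["region"] == "Fruitful Rim") & ~df["urban"]]
        df.loc[ca_idx[:config.n_ca_like], "seed_excluded"] = True
    return df


def _areas(config: ScenarioConfig, counties: pd.DataFrame, year: int):
    """(cropland_ha, treated_ha) arrays for one year."""
    y0, y1 = config.years
    frac = (year - y0) / (y1 - y0)
    tf0, tf1 = config.treated_frac
    tf = tf0 + (tf1 - tf0) * frac
    cropland = counties["cropland_base_ha"].to_numpy() * (1.0 + config.cropland_trend * frac)
    treated = np.minimum(cropland * tf * counties["treated_scale"].to_numpy(), cropland)
    treated = np.where(counties["urban"].to_numpy(), 0.0, treated)
    return cropland, treated


def _compound_weights(config: ScenarioConfig, counties: pd.DataFrame,
                      comp: CompoundSpec) -> np.ndarray:
    w = np.array([comp.weight(r) for r in counties["region"]])
    w[counties["urban"].to_numpy()] = 0.0
    if comp.chem_class == "NEO":  # seed treatments excluded in CA-like counties
        w[counties["seed_excluded"].to_numpy()] = 0.0
    return w


def _calibrate(config: ScenarioConfig, counties: pd.DataFrame):
    """Solve for (op_ratio, neo_scale) so planted national folds hit target.

    The two endpoint-year load balances are linear in the organophosphate
    end/start rate ratio x and the neonicotinoid adoption scale alpha, so a
    2x2 solve plants the configured fold-changes exactly.
    """
    if not config.calibrate:
        return 0.5, 1.0
    y0, y1 = config.years
    fixed = {"contact": [0.0, 0.0], "oral": [0.0, 0.0]}  # [y0, y1]
    op = {"contact": [0.0, 0.0], "oral": [0.0, 0.0]}
    neo = {"contact": 0.0, "oral": 0.0}  # y1 only; zero at y0 by construction
    _, treated0 = _areas(config, counties, y0)
    _, treated1 = _areas(config, counties, y1)
    for comp in config.compounds:
        w = _compound_weights(config, counties, comp)
        m0, m1 = float(w @ treated0), float(w @ treated1)
        for route, ld50 in (("contact", comp.contact_ld50), ("oral", comp.oral_ld50)):
            if comp.curve == "op_decline":
                op[route][0] += comp.base_rate * m0 / ld50
                op[route][1] += comp.base_rate * m1 / ld50
            elif comp.curve == "neo_adoption":
                r1 = comp.rate(y1, y0, y1, x=1.0, alpha=1.0)
                if comp.rate(y0, y0, y1, x=1.0, alpha=1.0) != 0.0:
                    raise ScenarioError(
                        f"{comp.compound_id}: adoption curve must be zero at the start year "
                        "for calibration")
                neo[route] += r1 * m1 / ld50
            else:
                fixed[route][0] += comp.rate(y0, y0, y1) * m0 / ld50
                fixed[route][1] += comp.rate(y1, y0, y1) * m1 / ld50
    targets = {"contact": config.target_contact_fold, "oral": config.target_oral_fold}
    a = np.array([[op["contact"][1], neo["contact"]],
                  [op["oral"][1], neo["oral"]]])
    b = np.array([targets["contact"] * (fixed["contact"][0] + op["contact"][0])
                  - fixed["contact"][1],
                  targets["oral"] * (fixed["oral"][0] + op["oral"][0])
                  - fixed["oral"][1]])
    try:
        x, alpha = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ScenarioError(f"fold-change calibration is singular: {exc}") from exc
    if not (0 < x <= 1 and alpha > 0):
        raise ScenarioError(
            f"calibration infeasible for targets {targets}: op_ratio={x:.4g}, "
            f"neo_scale={alpha:.4g}; adjust the catalog or targets")
    return float(x), float(alpha)


def _intent(config: ScenarioConfig, counties: pd.DataFrame,
            x: float, alpha: float) -> pd.DataFrame:
    """Pre-missingness kg per (county, year, compound), zero rows omitted."""
    y0, y1 = config.years
    frames = []
    for comp in config.compounds:
        w = _compound_weights(config, counties, comp)
        for year in config.year_list:
            rate = comp.rate(year, y0, y1, x=x, alpha=alpha)
            if rate == 0.0:
                continue
            _, treated = _areas(config, counties, year)
            kg = rate * w * treated
            nz = kg > 0
            if not nz.any():
                continue
            frames.append(pd.DataFrame({
                "compound": comp.compound_id,
                "class": comp.chem_class,
                "year": year,
                "fips": counties.loc[nz, "fips"].to_numpy(),
                "kg_low": kg[nz],
                "seed_excluded_flag": counties.loc[nz, "seed_excluded"].to_numpy(),
            }))
    if not frames:
        raise ScenarioError("scenario produces no insecticide use at all")
    intent = pd.concat(frames, ignore_index=True)
    intent["kg_high"] = intent["kg_low"] * intent["class"].map(config.multiplier_for)
    cols = ["compound", "class", "year", "fips", "kg_low", "kg_high",
            "seed_excluded_flag"]
    return (intent[cols].sort_values(["compound", "year", "fips"], kind="stable")
                        .reset_index(drop=True))


def _ground_truth(config: ScenarioConfig, counties: pd.DataFrame,
                  intent: pd.DataFrame, x: float, alpha: float) -> GroundTruth:
    ld = {(c.compound_id, "contact"): c.contact_ld50 for c in config.compounds}
    ld.update({(c.compound_id, "oral"): c.oral_ld50 for c in config.compounds})
    df = intent.copy()
    for route in ("contact", "oral"):
        ld50 = df["compound"].map(lambda c, r=route: ld[(c, r)])
        df[f"{route}_load"] = df["kg_low"] * KG_TO_UG / ld50
    grid = pd.MultiIndex.from_product(
        [counties["fips"], config.year_list], names=["fips", "year"])
    county_loads = (df.groupby(["fips", "year"])
                      .agg(kg_total=("kg_low", "sum"),
                           contact_load=("contact_load", "sum"),
                           oral_load=("oral_load", "sum"))
                      .reindex(grid, fill_value=0.0)
                      .reset_index())

    region_map = counties.set_index("fips")["region"]
    county_loads["region"] = county_loads["fips"].map(region_map)
    y0, y1 = config.years

    def folds(g):
        s = g.groupby("year")[["contact_load", "oral_load"]].sum()
        return pd.Series({
            "contact_fold": s.loc[y1, "contact_load"] / s.loc[y0, "contact_load"],
            "oral_fold": s.loc[y1, "oral_load"] / s.loc[y0, "oral_load"],
        })

    regional = (county_loads.groupby("region", sort=True)
                            .apply(folds, include_groups=False).reset_index())
    nat = folds(county_loads)
    return GroundTruth(
        national_folds={"contact": float(nat["contact_fold"]),
                        "oral": float(nat["oral_fold"])},
        regional_folds=regional,
        county_loads=county_loads.drop(columns="region"),
        calibration={"op_ratio": x, "neo_scale": alpha},
    )


def _apply_use_missingness(config: ScenarioConfig, counties: pd.DataFrame,
                           intent: pd.DataFrame,
                           rng: np.random.Generator) -> pd.DataFrame:
    if config.p_missing_use <= 0:
        return intent.copy()
    drop_mask = rng.random((config.n_counties, len(config.year_list))) < config.p_missing_use
    dropped = {(counties["fips"].iat[i], config.year_list[j])
               for i, j in zip(*np.nonzero(drop_mask))}
    keep = ~intent.apply(lambda r: (r["fips"], r["year"]) in dropped, axis=1)
    return intent.loc[keep].reset_index(drop=True)


def _landuse(config: ScenarioConfig, counties: pd.DataFrame,
             rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for year in sorted(config.census_years):
        cropland, treated = _areas(config, counties, year)
        rows.append(pd.DataFrame({
            "fips": counties["fips"],
            "year": year,
            "land_ha": counties["land_ha"],
            "cropland_ha": cropland,
            "treated_ha": treated,
        }))
    lu = pd.concat(rows, ignore_index=True)
    lu["withheld_cropland"] = rng.random(len(lu)) < config.p_withheld
    lu["withheld_treated"] = rng.random(len(lu)) < config.p_withheld
    lu.loc[lu["withheld_cropland"], "cropland_ha"] = np.nan
    lu.loc[lu["withheld_treated"], "treated_ha"] = np.nan
    return lu.sort_values(["fips", "year"], kind="stable").reset_index(drop=True)


def _toxicity(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def add(comp, route, value, units="ug/bee", bound="point",
            source_tier="regulatory", duration_days=2.0, life_stage="adult"):
        rows.append((comp.compound_id, comp.cas, route, value, units, bound,
                     source_tier, duration_days, life_stage))

    for k, comp in enumerate(config.compounds):
        truths = {"contact": comp.contact_ld50, "oral": comp.oral_ld50}
        if comp.tox_profile == "regulatory_points":
            for route, true in truths.items():
                for j in range(2):
                    v = true * 10 ** (config.tox_sigma_regulatory * rng.standard_normal())
                    if route == "contact" and j == 1:
                        add(comp, route, v / 1000.0, units="mg/bee")
                    else:
                        add(comp, route, v, duration_days=2.0 if route == "contact" else 4.0)
                for _ in range(2):
                    v = true * 10 ** (config.tox_sigma_other * rng.standard_normal())
                    add(comp, route, v, source_tier="other", duration_days=3.0)
            # records the four selection criteria must reject
            add(comp, "contact", truths["contact"] * 2, duration_days=28.0)
            add(comp, "oral", truths["oral"] * 0.5, life_stage="larva")
            if k == 0:
                add(comp, "other", 1.0)
                add(comp, "oral", 5.0, units="ppm")
        elif comp.tox_profile == "regulatory_bounds":
            for route, true in truths.items():
                add(comp, route, 0.8 * true, bound="greater_than")
                add(comp, route, true, bound="greater_than")
                add(comp, route, 4.0 * true, bound="less_than", source_tier="other")
        elif comp.tox_profile == "none":
            # present in the raw extract but unusable (larval test only)
            add(comp, "contact", comp.contact_ld50, life_stage="larva")
        else:
            raise ScenarioError(f"{comp.compound_id}: unknown tox profile "
                                f"{comp.tox_profile!r}")
    return pd.DataFrame(rows, columns=["compound", "cas", "route", "value", "units",
                                       "bound", "source_tier", "duration_days",
                                       "life_stage"])


def generate_scenario(config: ScenarioConfig) -> SyntheticData:
    """Generate all three source tables and the planted ground truth."""
    rng = np.random.default_rng(config.seed)
    counties = _counties(config, rng)
    x, alpha = _calibrate(config, counties)
    intent = _intent(config, counties, x, alpha)
    truth = _ground_truth(config, counties, intent, x, alpha)
    use = _apply_use_missingness(config, counties, intent, rng)
    landuse = _landuse(config, counties, rng)
    toxicity = _toxicity(config, rng)
    return SyntheticData(counties=counties, use=use, landuse=landuse,
                         toxicity=toxicity, truth=truth)


def generate_use_table(config: ScenarioConfig) -> pd.DataFrame:
    """The pesticide-use table alone (see :func:`generate_scenario`)."""
    return generate_scenario(config).use


def generate_landuse_table(config: ScenarioConfig) -> pd.DataFrame:
    """The census land-use table alone."""
    return generate_scenario(config).landuse


def generate_toxicity_records(config: ScenarioConfig) -> pd.DataFrame:
    """The raw toxicity-record table alone."""
    return generate_scenario(config).toxicity


def region_map(counties: pd.DataFrame) -> dict:
    """fips -> region dictionary from a counties frame."""
    return dict(zip(counties["fips"], counties["region"]))
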