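"""Scenario configuration for the synthetic source tables.

A scenario describes the study system the generator emulates: counties
grouped into the nine Farm Resource Regions, an insecticide catalog with
true contact/oral LD50s and per-year adoption curves, agricultural-census
land-use structure, and the missingness patterns of the real sources
(withheld census cells, county-years absent from the use data, dual
low/high weight estimates).

The default catalog mirrors the insecticide transition of 1997-2012 US row
crops: organophosphates declining, pyrethroids steady to rising, and
neonicotinoid seed treatments adopted from 2006 onward, concentrated in the
Heartland and Northern Great Plains.  Two generator parameters -- the
organophosphate end/start rate ratio and the neonicotinoid adoption scale
-- are calibrated at generation time by solving a 2x2 linear system so the
planted national fold-changes in oral and contact toxic load equal the
configured targets (9-fold and 1-fold by default) exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = ["REGIONS", "CompoundSpec", "ScenarioConfig", "ScenarioError",
           "default_catalog", "default_scenario", "scenario_from_yaml"]

#: The nine USDA Farm Resource Region labels.
REGIONS = (
    "Heartland",
    "Northern Crescent",
    "Northern Great Plains",
    "Prairie Gateway",
    "Eastern Uplands",
    "Southern Seaboard",
    "Fruitful Rim",
    "Basin and Range",
    "Mississippi Portal",
)

#: Regions where the planted neonicotinoid adoption is concentrated.
NEO_REGIONS = ("Heartland", "Northern Great Plains")


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class CompoundSpec:
    """One active ingredient in the synthetic use catalog.

    ``base_rate`` is the mean kg of active ingredient per treated hectare at
    the scenario start year; the ``curve`` shapes its trajectory:

    - ``constant``: base_rate every year
    - ``linear_rise``: base_rate * (1 + slope * (year - start))
    - ``op_decline``: base_rate * x ** frac(year), with x the calibrated
      end/start ratio shared by all declining compounds
    - ``neo_adoption``: 0 before ``start``, then
      alpha * base_rate * exp(growth * (year - start)) with alpha the
      calibrated adoption scale

    ``region_weights`` multiplies the rate per region (default 1
    everywhere).  ``tox_profile`` selects which kinds of toxicity records
    the generator emits for the compound.
    """

    compound_id: str
    cas: str
    chem_class: str
    moa_group: str
    contact_ld50: float  # true acute contact LD50, ug/bee
    oral_ld50: float  # true acute oral LD50, ug/bee
    base_rate: float  # kg ai per treated ha at the start year
    curve: str = "constant"
    curve_params: dict = field(default_factory=dict)
    region_weights: dict = field(default_factory=dict)
    tox_profile: str = "regulatory_points"

    def __post_init__(self):
        if not (self.contact_ld50 > 0 and self.oral_ld50 > 0):
            raise ScenarioError(f"{self.compound_id}: true LD50s must be positive")
        if self.base_rate < 0:
            raise ScenarioError(f"{self.compound_id}: adoption curve must be non-negative")
        if self.curve not in ("constant", "linear_rise", "op_decline", "neo_adoption"):
            raise ScenarioError(f"{self.compound_id}: unknown curve {self.curve!r}")

    def weight(self, region: str) -> float:
        return float(self.region_weights.get(region, 1.0))

    def rate(self, year: int, year0: int, year1: int,
             x: float = 1.0, alpha: float = 1.0) -> float:
        """kg/treated-ha in ``year`` given the calibrated (x, alpha)."""
        frac = (year - year0) / (year1 - year0)
        if self.curve == "constant":
            return self.base_rate
        if self.curve == "linear_rise":
            slope = float(self.curve_params.get("slope", 0.04))
            return self.base_rate * (1.0 + slope * (year - year0))
        if self.curve == "op_decline":
            return self.base_rate * x ** frac
        # neo_adoption
        start = int(self.curve_params.get("start", 2006))
        growth = float(self.curve_params.get("growth", 0.45))
        if year < start:
            return 0.0
        return alpha * self.base_rate * math.exp(growth * (year - start))


def default_catalog() -> tuple:
    """The default 12-compound catalog (true LD50s near published values).

    Non-neonicotinoid compounds carry reduced weight in the two
    neonicotinoid-adopting regions (corn/soy-dominated cropland receives
    less foliar insecticide), which keeps those regions' baseline load low
    and their planted oral fold-increases large.  The two fallback-tier
    compounds (tefluthrin: bounds only; oxamyl: no usable records) have
    negligible use, and oxamyl's true LD50s coincide with its carbamate
    group median so the fallback introduces no planted error.
    """
    base_rw = {r: 0.6 for r in NEO_REGIONS}
    neo_rw = {r: (1.0 if r in NEO_REGIONS else 0.02) for r in REGIONS}
    return (
        CompoundSpec("chlorpyrifos", "2921-88-2", "OP", "1B", 0.059, 0.25,
                     1.2, "op_decline", region_weights=base_rw),
        CompoundSpec("malathion", "121-75-5", "OP", "1B", 0.20, 0.40,
                     0.8, "op_decline", region_weights=base_rw),
        CompoundSpec("carbaryl", "63-25-2", "CARB", "1A", 1.1, 0.14,
                     0.40, "constant", region_weights=base_rw),
        CompoundSpec("lambda-cyhalothrin", "91465-08-6", "PYR", "3A", 0.038, 0.91,
                     0.02, "linear_rise", {"slope": 0.04}, region_weights=base_rw),
        CompoundSpec("bifenthrin", "82657-04-3", "PYR", "3A", 0.015, 0.10,
                     0.02, "constant", region_weights=base_rw),
        CompoundSpec("imidacloprid", "138261-41-3", "NEO", "4A", 0.081, 0.0037,
                     1.0, "neo_adoption", region_weights=neo_rw),
        CompoundSpec("clothianidin", "210880-92-5", "NEO", "4A", 0.044, 0.00368,
                     0.6, "neo_adoption", region_weights=neo_rw),
        CompoundSpec("fipronil", "120068-37-3", "FIP", "2B", 0.0059, 0.00417,
                     0.002, "constant", region_weights=base_rw),
        CompoundSpec("spinosad", "168316-95-8", "SPIN", "5", 0.0036, 0.057,
                     0.005, "constant", region_weights=base_rw),
        CompoundSpec("bacillus-thuringiensis", "68038-71-1", "BIO", "11A", 100.0, 100.0,
                     0.05, "constant", region_weights=base_rw),
        CompoundSpec("tefluthrin", "79538-32-2", "PYR", "3A", 0.28, 0.17,
                     0.001, "constant", region_weights=base_rw,
                     tox_profile="regulatory_bounds"),
        # true LD50s equal the CARB (1A) group median (carbaryl) by design
        CompoundSpec("oxamyl", "23135-22-0", "CARB", "1A", 1.1, 0.14,
                     0.0005, "constant", region_weights=base_rw,
                     tox_profile="none"),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic study scenario."""

    n_counties: int = 90
    years: tuple = (1997, 2012)  # inclusive range
    census_years: tuple = (1997, 2002, 2007, 2012)
    compounds: tuple = field(default_factory=default_catalog)
    #: explicit county -> region labels (length n_counties); None = round robin
    region_assignment: tuple | None = None
    #: probability a (county, year) is entirely absent from the use table
    p_missing_use: float = 0.05
    #: probability a census cropland/treated cell is withheld
    p_withheld: float = 0.10
    #: kg_high = kg_low * multiplier; scalar or per-chemical-class dict
    high_multiplier: float | dict = 1.5
    n_urban: int = 2  # counties with no agricultural insecticide use at all
    n_ca_like: int = 3  # Fruitful Rim counties with seed treatments excluded
    #: planted national fold-changes (end year / start year)
    target_oral_fold: float = 9.0
    target_contact_fold: float = 1.0
    calibrate: bool = True
    #: national proportion of cropland treated at start and end year
    treated_frac: tuple = (0.15, 0.26)
    cropland_trend: float = -0.12  # relative change in cropland over the period
    #: log10-scale sd of point-estimate toxicity records by source tier
    tox_sigma_regulatory: float = 0.0
    tox_sigma_other: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ScenarioError(f"seed must be an integer, got {self.seed!r}")
        if not self.compounds:
            raise ScenarioError("compound catalog is empty")
        if self.n_counties < len(REGIONS):
            raise ScenarioError(f"need at least {len(REGIONS)} counties")
        y0, y1 = self.years
        if y1 <= y0:
            raise ScenarioError("years must be an increasing (start, end) range")
        if not set(self.census_years) <= set(range(y0, y1 + 1)):
            raise ScenarioError("census_years must lie within years")
        for p, name in ((self.p_missing_use, "p_missing_use"),
                        (self.p_withheld, "p_withheld")):
            if not 0 <= p <= 1:
                raise ScenarioError(f"{name} must be in [0, 1]")
        mults = (self.high_multiplier.values()
                 if isinstance(self.high_multiplier, dict)
                 else [self.high_multiplier])
        if any(m < 1 for m in mults):
            raise ScenarioError("high_multiplier must be >= 1")
        if self.region_assignment is not None:
            if len(self.region_assignment) != self.n_counties:
                raise ScenarioError("region_assignment length must equal n_counties")
            if not set(self.region_assignment) <= set(REGIONS):
                raise ScenarioError("region_assignment contains unknown region labels")

    @property
    def year_list(self) -> list:
        return list(range(self.years[0], self.years[1] + 1))

    def region_of(self, i: int) -> str:
        if self.region_assignment is not None:
            return self.region_assignment[i]
        return REGIONS[i % len(REGIONS)]

    def multiplier_for(self, chem_class: str) -> float:
        if isinstance(self.high_multiplier, dict):
            return float(self.high_multiplier.get(chem_class, 1.0))
        return float(self.high_multiplier)

    def with_(self, **kwargs) -> "ScenarioConfig":
        """A copy with fields replaced (convenience for tests/sensitivity)."""
        return replace(self, **kwargs)


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default study scenario with a given seed."""
    return ScenarioConfig(seed=seed, **overrides)


def scenario_from_yaml(path, seed: int | None = None) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML mapping.

    Recognized keys are the ScenarioConfig field names; ``compounds`` may be
    a list of mappings with CompoundSpec field names (absent = default
    catalog).  A ``seed`` argument overrides the file value.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ScenarioError(f"scenario file {path} must contain a mapping")
    if "compounds" in raw:
        raw["compounds"] = tuple(CompoundSpec(**c) for c in raw["compounds"])
    for key in ("years", "census_years", "treated_frac", "region_assignment"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = int(seed)
    return ScenarioConfig(**raw)
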