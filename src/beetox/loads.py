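"""Bee toxic-load accounting per county-year.

Toxic load is the total number of honey-bee lethal doses represented by the
insecticides applied in an area:

    toxic_load(route) = sum_ai  Weight_ai / LD50_ai(route)

with weight converted from kg to ug (x 1e9) before dividing by the LD50 in
ug/bee, so the sum is a count of bee LD50s.  Contact and oral loads are
computed separately, with a per-chemical-class breakdown alongside, using
either the "low" (default, conservative) or "high" weight estimate.

County-years absent from the use data are filled by linear interpolation of
kg and both loads; leading/trailing gaps are filled by constant extension of
the nearest observed year, and counties with no records in any year are
assumed to be zero throughout.  Filled rows are flagged ``interpolated``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .consensus import ROUTES

logger = logging.getLogger(__name__)

__all__ = ["KG_TO_UG", "compute_toxic_load", "fill_missing_series", "class_series",
           "annual_totals", "load_value_columns"]

#: kg -> ug conversion so Weight/LD50 yields a count of bee lethal doses.
KG_TO_UG = 1e9

_BASE_COLS = ["kg_total", "contact_load", "oral_load"]


def load_value_columns(loads: pd.DataFrame) -> list:
    """The numeric toxic-load columns (totals plus per-class breakdown)."""
    per_class = [c for c in loads.columns
                 if any(c.startswith(p + "_") for p in ("kg", "contact", "oral"))
                 and c not in _BASE_COLS and c not in ("contact_load", "oral_load")]
    return _BASE_COLS + per_class


def compute_toxic_load(use: pd.DataFrame, consensus: pd.DataFrame,
                       variant: str = "low") -> pd.DataFrame:
    """Contact and oral bee toxic load per county-year (Weight/LD50 summed).

    Parameters
    ----------
    use : DataFrame
        Use records with columns fips, year, compound, class, kg_low, kg_high.
    consensus : DataFrame
        Consensus LD50 table (compound, route, ld50_ug_per_bee); must cover
        every compound in ``use`` for both routes.
    variant : {"low", "high"}
        Which weight estimate to use.

    Returns
    -------
    DataFrame keyed (fips, year) with kg_total, contact_load, oral_load,
    per-class columns ``kg_<CLS>``, ``contact_<CLS>``, ``oral_<CLS>``, the
    estimate variant and an ``interpolated`` flag (False here).
    """
    if variant not in ("low", "high"):
        raise ValueError(f"variant must be 'low' or 'high', got {variant!r}")
    kg_col = f"kg_{variant}"
    df = use.copy()

    neg = df[kg_col] < 0
    if neg.any():
        logger.warning("compute_toxic_load: rejecting %d row(s) with negative kg",
                       int(neg.sum()))
        df = df.loc[~neg]

    ld50 = {route: consensus.loc[consensus["route"] == route]
            .set_index("compound")["ld50_ug_per_bee"] for route in ROUTES}
    missing = [c for c in df["compound"].unique()
               if c not in ld50["contact"].index or c not in ld50["oral"].index]
    if missing:
        raise KeyError(f"no consensus LD50 for compound(s): {sorted(missing)}")

    df["kg"] = df[kg_col].astype(float)
    for route in ROUTES:
        df[f"{route}_doses"] = df["kg"] * KG_TO_UG / df["compound"].map(ld50[route]).to_numpy()

    totals = (df.groupby(["fips", "year"], sort=True)
                .agg(kg_total=("kg", "sum"),
                     contact_load=("contact_doses", "sum"),
                     oral_load=("oral_doses", "sum")))
    by_class = (df.groupby(["fips", "year", "class"], sort=True)
                  .agg(kg=("kg", "sum"),
                       contact=("contact_doses", "sum"),
                       oral=("oral_doses", "sum"))
                  .unstack("class", fill_value=0.0))
    by_class.columns = [f"{measure}_{cls}" for measure, cls in by_class.columns]

    out = totals.join(by_class).reset_index()
    out["estimate_variant"] = variant
    out["interpolated"] = False
    return out


def fill_missing_series(loads: pd.DataFrame, years,
                        fips_universe=None) -> pd.DataFrame:
    """Fill missing county-years of a load table.

    Interior gaps are linearly interpolated independently for every numeric
    load column; leading/trailing gaps take the nearest observed value
    (linear interpolation being undefined there); counties in
    ``fips_universe`` with no observed year at all are zero-filled.  Observed
    rows are returned unchanged; filled rows have ``interpolated=True``.
    """
    years = list(years)
    value_cols = load_value_columns(loads)
    variant = loads["estimate_variant"].iloc[0] if len(loads) else "low"
    extra = set(fips_universe) if fips_universe is not None else set()
    fips_all = sorted(set(loads["fips"]) | extra)

    full_index = pd.MultiIndex.from_product([fips_all, years], names=["fips", "year"])
    wide = (loads.set_index(["fips", "year"])[value_cols]
                 .reindex(full_index))
    observed = ~wide[value_cols[0]].isna()

    def fill_county(g: pd.DataFrame) -> pd.DataFrame:
        if g.notna().to_numpy().any():
            g = g.interpolate(method="linear", limit_area="inside")
            g = g.ffill().bfill()
        else:
            g = g.fillna(0.0)
        return g

    filled = wide.groupby(level="fips", group_keys=False)[value_cols].apply(fill_county)
    out = filled.reset_index()
    out["estimate_variant"] = variant
    out["interpolated"] = ~observed.to_numpy()
    n_filled = int(out["interpolated"].sum())
    if n_filled:
        logger.info("fill_missing_series: filled %d of %d county-years",
                    n_filled, len(out))
    return out


def class_series(loads: pd.DataFrame, region_map: dict | None = None) -> pd.DataFrame:
    """Annual kg/contact/oral series per chemical class, national or regional.

    Parameters
    ----------
    loads : DataFrame
        County-year load table with per-class columns.
    region_map : dict, optional
        fips -> region label; when given the series are per region, else
        national.

    Returns a tidy table (region?, year, class, kg, contact_load, oral_load).
    """
    per_class = [c for c in load_value_columns(loads) if c not in _BASE_COLS]
    df = loads[["fips", "year"] + per_class].copy()
    keys = ["year"]
    if region_map is not None:
        df["region"] = df["fips"].map(region_map)
        keys = ["region", "year"]
    agg = df.groupby(keys, sort=True)[per_class].sum()
    long = agg.reset_index().melt(id_vars=keys, var_name="measure_class",
                                  value_name="value")
    split = long["measure_class"].str.split("_", n=1, expand=True)
    long["measure"], long["class"] = split[0], split[1]
    out = (long.pivot_table(index=keys + ["class"], columns="measure",
                            values="value", aggfunc="first")
               .reset_index()
               .rename(columns={"kg": "kg", "contact": "contact_load",
                                "oral": "oral_load"}))
    out.columns.name = None
    return out


def annual_totals(loads: pd.DataFrame, region_map: dict | None = None) -> pd.DataFrame:
    """Annual kg_total/contact_load/oral_load series, national or per region."""
    df = loads[["fips", "year"] + _BASE_COLS].copy()
    keys = ["year"]
    if region_map is not None:
        df["region"] = df["fips"].map(region_map)
        keys = ["region", "year"]
    return df.groupby(keys, sort=True)[_BASE_COLS].sum().reset_index()
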