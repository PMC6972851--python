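r"""Extent-intensity decomposition of bee toxic load.

Toxic load per hectare of county land factors multiplicatively into

    load/ha = (cropland/land) x (treated/cropland) x (kg/treated) x (load/kg)
              \------------- extent -------------/   \------ intensity -----/

i.e. cropland fraction, proportion of cropland treated with insecticides,
application rate, and potency (bee LD50s per kg, weight-weighted across the
compounds actually applied).  Components are computed for agricultural
census years only, after imputing withheld census cells with the county
mean over other years (zero when withheld everywhere).  Regional and
national summaries are ratio-of-sums, not means of county ratios, so the
multiplicative identity survives aggregation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .loads import KG_TO_UG
from .trends import fold_change

logger = logging.getLogger(__name__)

__all__ = ["impute_census", "county_components", "regional_summary",
           "component_fold_changes", "COMPONENT_MEASURES"]

_AREA_FIELDS = ("land_ha", "cropland_ha", "treated_ha")

#: measures reported by component_fold_changes
COMPONENT_MEASURES = ("cropland_ha", "treated_ha", "app_rate",
                      "potency_contact", "potency_oral",
                      "contact_load", "oral_load")


def impute_census(landuse: pd.DataFrame) -> pd.DataFrame:
    """Impute withheld census cells with the county mean over other years.

    Withheld cells are NaN in the area columns (optionally accompanied by
    ``withheld_<field>`` flags).  Each is replaced by the arithmetic mean of
    the county's non-missing values of that field in other years, or zero
    when the field is withheld in every year.  ``imputed_<field>`` flags are
    set; afterwards treated <= cropland <= land is enforced by clamping
    (flagged ``clamped``).  Row order is preserved.
    """
    df = landuse.copy()
    for field in _AREA_FIELDS:
        if field not in df.columns:
            raise ValueError(f"land-use table missing column {field!r}")
        vals = pd.to_numeric(df[field], errors="coerce")
        missing = vals.isna()
        county_mean = vals.groupby(df["fips"]).transform("mean")
        df[field] = vals.where(~missing, county_mean.fillna(0.0))
        df[f"imputed_{field}"] = missing
    n_imputed = int(df[[f"imputed_{f}" for f in _AREA_FIELDS]].to_numpy().sum())
    if n_imputed:
        logger.info("impute_census: imputed %d withheld cell(s)", n_imputed)

    clamp_crop = df["cropland_ha"] > df["land_ha"]
    df.loc[clamp_crop, "cropland_ha"] = df.loc[clamp_crop, "land_ha"]
    clamp_treat = df["treated_ha"] > df["cropland_ha"]
    df.loc[clamp_treat, "treated_ha"] = df.loc[clamp_treat, "cropland_ha"]
    df["clamped"] = clamp_crop | clamp_treat
    if df["clamped"].any():
        logger.info("impute_census: clamped %d row(s) to keep treated <= cropland <= land",
                    int(df["clamped"].sum()))
    return df


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived component columns to a table of area/kg/load sums."""
    out = df.copy()
    land = out["land_ha"].to_numpy(dtype=float)
    crop = out["cropland_ha"].to_numpy(dtype=float)
    treated = out["treated_ha"].to_numpy(dtype=float)
    kg = out["kg_total"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        out["extent_land"] = np.where(land > 0, treated / land, np.nan)
        out["cropland_frac"] = np.where(land > 0, crop / land, np.nan)
        out["prop_cropland_treated"] = np.where(crop > 0, treated / crop, np.nan)
        out["app_rate"] = np.where(treated > 0, kg / treated, np.nan)
        for route in ("contact", "oral"):
            load = out[f"{route}_load"].to_numpy(dtype=float)
            out[f"potency_{route}"] = np.where(kg > 0, load / kg, np.nan)
            out[f"intensity_{route}"] = np.where(treated > 0, load / treated, np.nan)
            out[f"load_per_ha_{route}"] = np.where(land > 0, load / land, np.nan)
    out["undefined_intensity"] = treated <= 0
    return out


def county_components(loads: pd.DataFrame, landuse: pd.DataFrame,
                      census_years) -> pd.DataFrame:
    """Per-county, per-census-year decomposition components.

    ``landuse`` must already be imputed (:func:`impute_census`).  Counties
    with toxic load but no land-use row are logged and excluded; counties
    with no treated area keep their per-land-ha loads but have rate,
    potency and intensity flagged undefined (NaN), never coerced to zero.
    """
    census_years = sorted(set(census_years))
    lo = loads[loads["year"].isin(census_years)][
        ["fips", "year", "kg_total", "contact_load", "oral_load"]]
    lu = landuse[landuse["year"].isin(census_years)][
        ["fips", "year", *_AREA_FIELDS]]
    merged = lo.merge(lu, on=["fips", "year"], how="outer", indicator=True)

    unmatched = merged.loc[merged["_merge"] == "left_only", "fips"].unique()
    if len(unmatched):
        logger.warning("county_components: %d count(y/ies) in loads lack land use "
                       "and were excluded: %s", len(unmatched),
                       ", ".join(sorted(map(str, unmatched))[:10]))
    merged = merged[merged["_merge"] != "left_only"].drop(columns="_merge")
    # land-use rows without any use record mean zero applied kg
    for col in ("kg_total", "contact_load", "oral_load"):
        merged[col] = merged[col].fillna(0.0)
    merged = merged.sort_values(["fips", "year"], kind="stable").reset_index(drop=True)
    return _derive(merged)


def regional_summary(components: pd.DataFrame, region_map: dict,
                     year: int | None = None,
                     national_label: str = "Contiguous US") -> pd.DataFrame:
    """Table-1-style regional (and national) aggregates from county sums.

    All ratios are computed from regional sums (sum treated / sum land,
    sum load / sum treated, ...), never as means of county ratios.
    """
    df = components if year is None else components[components["year"] == year]
    df = df.copy()
    unknown = set(df["fips"].map(region_map).pipe(lambda s: df.loc[s.isna(), "fips"]))
    if unknown:
        raise KeyError(f"counties with unknown region: {sorted(unknown)[:10]}")
    df["region"] = df["fips"].map(region_map)

    sums_cols = [*_AREA_FIELDS, "kg_total", "contact_load", "oral_load"]
    regional = df.groupby(["region", "year"], sort=True)[sums_cols].sum().reset_index()
    national = df.groupby("year", sort=True)[sums_cols].sum().reset_index()
    national.insert(0, "region", national_label)
    out = pd.concat([regional, national], ignore_index=True)
    return _derive(out)


def format_table1(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a regional summary in the reporting dialect of the headline
    table: land in millions of ha, extent as a percentage with one decimal,
    intensities and per-ha loads in billions of bee LD50s with two decimals.
    """
    out = pd.DataFrame({
        "region": summary["region"],
        "year": summary["year"],
        "land_area_mil_ha": (summary["land_ha"] / 1e6).round(1),
        "extent_pct_ha_treated": (100 * summary["extent_land"]).round(1),
        "pct_cropland_treated": (100 * summary["prop_cropland_treated"]).round(1),
        "contact_intensity_bil_per_treated_ha":
            (summary["intensity_contact"] / KG_TO_UG).round(2),
        "oral_intensity_bil_per_treated_ha":
            (summary["intensity_oral"] / KG_TO_UG).round(2),
        "contact_load_bil_per_ha": (summary["load_per_ha_contact"] / KG_TO_UG).round(2),
        "oral_load_bil_per_ha": (summary["load_per_ha_oral"] / KG_TO_UG).round(2),
    })
    return out


def component_fold_changes(components: pd.DataFrame, y0: int, y1: int,
                           region_map: dict | None = None,
                           national_label: str = "Contiguous US") -> pd.DataFrame:
    """Response ratios value(y1)/value(y0) for each decomposition component.

    Ratios are reported for total cropland, cropland treated, application
    rate, potency (contact and oral) and toxic load (contact and oral), at
    the national level and -- when ``region_map`` is given -- per region.
    A zero baseline leaves that ratio NaN (flagged, not infinity).
    """
    if region_map is None:
        rm = {f: "_all_" for f in components["fips"].unique()}
        summary = regional_summary(components, rm, national_label=national_label)
        summary = summary[summary["region"] == national_label]
    else:
        summary = regional_summary(components, region_map, national_label=national_label)
    for y in (y0, y1):
        if y not in set(summary["year"]):
            raise ValueError(f"year {y} not present in components")

    rows = []
    for region, g in summary.groupby("region", sort=True):
        g = g.set_index("year")
        for measure in COMPONENT_MEASURES:
            v0 = float(g.loc[y0, measure])
            v1 = float(g.loc[y1, measure])
            if v0 > 0:
                ratio = fold_change(v0, v1)
            else:
                ratio = float("nan")
            rows.append((region, measure, v0, v1, ratio))
    return pd.DataFrame(rows, columns=["region", "measure",
                                       f"value_{y0}", f"value_{y1}", "fold_change"])
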