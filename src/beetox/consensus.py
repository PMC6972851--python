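"""Honey-bee acute LD50 standardization, filtering, and consensus selection.

Raw toxicity records (compiled in the style of ECOTOX / PPDB extracts) are
first standardized and filtered to acute adult honey-bee tests: exposure
time of 4 days or less, contact or oral route, adult bees, and a positive
LD50 expressed in ug/bee (mg/bee values are converted by x1000; other units
are dropped).

One consensus contact and one consensus oral LD50 per compound is then
selected by a strict rule ladder, preferring point estimates from
regulatory sources (which use standardized protocols) and falling back
through unbounded ("less than" / "greater than") estimates to mode-of-action
group medians and finally the median over all insecticides:

  tier 1  geometric mean of regulatory point estimates
  tier 2  geometric mean of other-source point estimates
  tier 3  regulatory unbounded: min over "less than" bounds if any,
          else max over "greater than" bounds
  tier 4  other-source unbounded, same bound rule
  tier 5  median of tier-1..4 consensus values in the compound's
          mode-of-action (IRAC) group
  tier 6  median of tier-1..4 consensus values over all compounds

"Less than" bounds take precedence within tiers 3-4 because an upper limit
on the LD50 is informative and hazard-conservative.  Medians of even-count
sets are arithmetic midpoints.  Duplicated records are not de-duplicated
before the geometric mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusError",
    "ConsensusLD50",
    "standardize_and_filter",
    "consensus_ld50",
    "consensus_table",
    "moa_median_table",
    "ROUTES",
]

ROUTES = ("contact", "oral")

_VALID_ROUTE = {"contact", "oral", "other"}
_VALID_UNITS = {"ug/bee", "mg/bee", "other"}
_VALID_BOUND = {"point", "less_than", "greater_than"}
_VALID_TIER = {"regulatory", "other"}
_VALID_STAGE = {"adult", "larva", "other"}


class ConsensusError(RuntimeError):
    """Raised when the consensus procedure is undefined (empty universe)."""


@dataclass(frozen=True)
class ConsensusLD50:
    """Per-compound, per-route consensus acute LD50 (ug/bee)."""

    compound_id: str
    route: str
    value: float
    tier: int  # 1..6, the ladder rule that produced the value
    n_records: int  # records used (0 for tiers 5-6)


def _normalize_units(u: str) -> str:
    return str(u).replace("µ", "u").replace("μ", "u").strip().lower()


def standardize_and_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Standardize units and apply the four acute-test selection criteria.

    Returns the retained rows (stable order, index reset) with all values in
    ug/bee.  Rows with invalid vocabulary or non-positive values are rejected
    with a logged reason, never an exception.
    """
    req = {"compound", "route", "value", "units", "bound", "source_tier",
           "duration_days", "life_stage"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"toxicity table missing columns: {sorted(missing)}")

    df = records.copy().reset_index(drop=True)
    df["units"] = df["units"].map(_normalize_units)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    reasons = pd.Series("", index=df.index)

    def flag(mask, reason):
        sel = mask & (reasons == "")
        reasons[sel] = reason

    flag(~df["route"].isin(_VALID_ROUTE), "unknown route")
    flag(~df["units"].isin(_VALID_UNITS), "unknown units")
    flag(~df["bound"].isin(_VALID_BOUND), "unknown bound type")
    flag(~df["source_tier"].isin(_VALID_TIER), "unknown source tier")
    flag(~df["life_stage"].isin(_VALID_STAGE), "unknown life stage")
    flag(~(df["value"] > 0), "non-positive or missing value")

    # unit standardization before the unit criterion
    mg = (df["units"] == "mg/bee") & (reasons == "")
    df.loc[mg, "value"] = df.loc[mg, "value"] * 1000.0
    df.loc[mg, "units"] = "ug/bee"

    flag(df["units"] != "ug/bee", "units not standardizable to ug/bee")
    flag(df["route"] == "other", "route neither contact nor oral")
    flag(df["life_stage"] != "adult", "not an adult-bee test")
    flag(pd.to_numeric(df["duration_days"], errors="coerce").isna()
         | (pd.to_numeric(df["duration_days"], errors="coerce") > 4),
         "exposure time over 4 days")

    rejected = reasons != ""
    if rejected.any():
        for reason, cnt in reasons[rejected].value_counts().items():
            logger.info("standardize_and_filter: rejected %d record(s): %s", cnt, reason)
    return df.loc[~rejected].reset_index(drop=True)


def _geomean(v: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(v))))


def _tier_1_to_4(recs: pd.DataFrame):
    """Apply ladder rules 1-4 to one compound's records for one route.

    Returns (value, tier, n_records) or None when no rule applies.
    """
    points = recs[recs["bound"] == "point"]
    for tier, src in ((1, "regulatory"), (2, "other")):
        sel = points[points["source_tier"] == src]
        if len(sel):
            return _geomean(sel["value"].to_numpy()), tier, len(sel)
    unbounded = recs[recs["bound"] != "point"]
    for tier, src in ((3, "regulatory"), (4, "other")):
        sel = unbounded[unbounded["source_tier"] == src]
        if len(sel):
            lt = sel[sel["bound"] == "less_than"]
            if len(lt):  # informative upper limits take precedence
                return float(lt["value"].min()), tier, len(lt)
            gt = sel[sel["bound"] == "greater_than"]
            return float(gt["value"].max()), tier, len(gt)
    return None


def consensus_ld50(records_for_compound: pd.DataFrame, route: str,
                   compound_id: str | None = None,
                   moa_median: float | None = None,
                   global_median: float | None = None) -> ConsensusLD50:
    """Consensus LD50 for one compound and route via the rule ladder.

    ``records_for_compound`` must already be standardized/filtered.  When no
    tier-1..4 rule applies, ``moa_median`` (tier 5) and then
    ``global_median`` (tier 6) are used; if neither is available the
    procedure is undefined and :class:`ConsensusError` is raised.
    """
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}, got {route!r}")
    recs = records_for_compound[records_for_compound["route"] == route]
    if compound_id is None:
        ids = records_for_compound["compound"].unique()
        compound_id = str(ids[0]) if len(ids) else "<unknown>"
    hit = _tier_1_to_4(recs)
    if hit is not None:
        value, tier, n = hit
        return ConsensusLD50(compound_id, route, value, tier, n)
    if moa_median is not None and np.isfinite(moa_median):
        return ConsensusLD50(compound_id, route, float(moa_median), 5, 0)
    if global_median is not None and np.isfinite(global_median):
        return ConsensusLD50(compound_id, route, float(global_median), 6, 0)
    raise ConsensusError(
        f"no consensus rule applies for {compound_id}/{route} and no fallback medians exist")


def moa_median_table(consensus: pd.DataFrame, moa_table: dict) -> pd.DataFrame:
    """Per mode-of-action group, per route median of tier-1..4 consensus values.

    ``consensus`` must contain only tier-1..4 rows (columns compound, route,
    ld50_ug_per_bee, tier).  Groups without any tier-1..4 member are absent.
    """
    if len(consensus) and (consensus["tier"] > 4).any():
        raise ValueError("moa_median_table expects only tier 1-4 consensus rows")
    df = consensus.copy()
    df["moa_group"] = df["compound"].map(moa_table)
    df = df.dropna(subset=["moa_group"])
    out = (df.groupby(["moa_group", "route"], sort=True)["ld50_ug_per_bee"]
             .median().reset_index()
             .rename(columns={"ld50_ug_per_bee": "median_ld50_ug_per_bee"}))
    return out


def consensus_table(records: pd.DataFrame, compounds, moa_table: dict) -> pd.DataFrame:
    """Consensus contact and oral LD50 for every compound in the use catalog.

    Parameters
    ----------
    records : DataFrame
        Standardized/filtered toxicity records (see
        :func:`standardize_and_filter`).
    compounds : sequence of str
        Every compound that appears in the use data; each receives exactly
        one contact and one oral consensus row.
    moa_table : dict
        compound id -> mode-of-action group label; must cover ``compounds``.

    Returns
    -------
    DataFrame with columns compound, route, ld50_ug_per_bee, tier, n_records.
    """
    compounds = list(dict.fromkeys(compounds))
    uncovered = [c for c in compounds if c not in moa_table]
    if uncovered:
        raise ValueError(f"moa_table does not cover compounds: {uncovered}")
    by_compound = dict(tuple(records.groupby("compound", sort=False)))
    empty = records.iloc[0:0]

    # pass 1: tiers 1-4
    rows = []
    pending = []
    for comp in compounds:
        recs = by_compound.get(comp, empty)
        for route in ROUTES:
            hit = _tier_1_to_4(recs[recs["route"] == route])
            if hit is not None:
                value, tier, n = hit
                rows.append((comp, route, value, tier, n))
            else:
                pending.append((comp, route))
    direct = pd.DataFrame(rows, columns=["compound", "route", "ld50_ug_per_bee",
                                         "tier", "n_records"])

    if pending:
        if direct.empty:
            raise ConsensusError(
                "no compound has a tier 1-4 value anywhere; the global-median fallback "
                "is undefined")
        moa_med = moa_median_table(direct, moa_table)
        moa_lookup = {(r.moa_group, r.route): r.median_ld50_ug_per_bee
                      for r in moa_med.itertuples()}
        global_med = {route: float(direct.loc[direct["route"] == route,
                                              "ld50_ug_per_bee"].median())
                      for route in ROUTES}
        for comp, route in pending:
            med = moa_lookup.get((moa_table[comp], route))
            if med is not None:
                rows.append((comp, route, float(med), 5, 0))
            else:
                gm = global_med.get(route)
                if gm is None or not np.isfinite(gm):
                    raise ConsensusError(
                        f"no tier 1-4 value exists for route {route!r}; "
                        "global median undefined")
                rows.append((comp, route, gm, 6, 0))

    out = pd.DataFrame(rows, columns=["compound", "route", "ld50_ug_per_bee",
                                      "tier", "n_records"])
    out = out.sort_values(["compound", "route"], kind="stable").reset_index(drop=True)
    return out
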