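"""Toxicity-record filtering and the six-tier consensus ladder."""

import math

import numpy as np
import pandas as pd
import pytest

from beetox import (ConsensusError, consensus_table, moa_median_table,
                    standardize_and_filter)
from conftest import toxicity_frame

OK = dict(units="ug/bee", bound="point", source_tier="regulatory",
          duration_days=2.0, life_stage="adult")


def rec(compound="a", route="oral", value=3.0, **overrides):
    row = {"compound": compound, "route": route, "value": value, **OK}
    row.update(overrides)
    return row


def frame(*rows):
    return toxicity_frame([(r["compound"], r["route"], r["value"], r["units"],
                            r["bound"], r["source_tier"], r["duration_days"],
                            r["life_stage"]) for r in rows])


class TestStandardizeAndFilter:
    @pytest.mark.parametrize("override,kept", [
        ({}, True),
        ({"duration_days": 4.0}, True),
        ({"duration_days": 7.0}, False),        # acute window is <= 4 days
        ({"life_stage": "larva"}, False),        # adult tests only
        ({"route": "other"}, False),
        ({"units": "ppm"}, False),
        ({"value": -1.0}, False),
        ({"value": 0.0}, False),
        ({"bound": "approximately"}, False),     # unknown vocabulary
    ])
    def test_selection_criteria(self, override, kept):
        out = standardize_and_filter(frame(rec(**override)))
        assert (len(out) == 1) == kept

    def test_mg_per_bee_converted_before_unit_criterion(self):
        out = standardize_and_filter(
            frame(rec("a", "oral", 0.01, units="mg/bee")))
        assert len(out) == 1
        assert out.loc[0, "value"] == pytest.approx(10.0)
        assert out.loc[0, "units"] == "ug/bee"

    def test_unicode_microgram_units_accepted(self):
        out = standardize_and_filter(frame(rec("a", "contact", 1.0, units="µg/bee")))
        assert len(out) == 1

    def test_idempotent(self):
        raw = frame(rec("a", "oral", 3.0), rec("a", "contact", 7.0, duration_days=9),
                    rec("b", "oral", 0.2, units="mg/bee"))
        once = standardize_and_filter(raw)
        twice = standardize_and_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_invalid_rows_rejected_without_crash(self):
        raw = frame(rec("a", "dermal", 3.0),  # unknown route vocabulary
                    rec("a", "oral", 3.0))
        out = standardize_and_filter(raw)
        assert len(out) == 1


def six_tier_fixture():
    """Hand-built records exercising every ladder tier, per route.

    Expected (both routes, hand-computed):
      A: regulatory points {1, 4}      -> geomean 2.0, tier 1
      B: other point 5 + reg "<2"      -> 5.0, tier 2 (points beat bounds)
      C: regulatory ">11" only         -> 11.0, tier 3 (max of greater-thans)
      D: other "<8" and "<6"           -> 6.0, tier 4 (min of less-thans)
      E: no records, MoA group g1={A,B} -> median{2, 5} = 3.5, tier 5
      F: no records, lone MoA group g9  -> global median{2,5,11,6} = 5.5, tier 6
    """
    rows = []
    for route in ("contact", "oral"):
        rows += [rec("A", route, 1.0), rec("A", route, 4.0),
                 rec("B", route, 5.0, source_tier="other"),
                 rec("B", route, 2.0, bound="less_than"),
                 rec("C", route, 11.0, bound="greater_than"),
                 rec("D", route, 8.0, bound="less_than", source_tier="other"),
                 rec("D", route, 6.0, bound="less_than", source_tier="other")]
    moa = {"A": "g1", "B": "g1", "C": "g2", "D": "g2", "E": "g1", "F": "g9"}
    return frame(*rows), moa


EXPECTED_TIERS = {"A": (2.0, 1), "B": (5.0, 2), "C": (11.0, 3),
                  "D": (6.0, 4), "E": (3.5, 5), "F": (5.5, 6)}


class TestConsensusLadder:
    def test_all_six_tiers_match_hand_computed_values(self):
        records, moa = six_tier_fixture()
        clean = standardize_and_filter(records)
        out = consensus_table(clean, list("ABCDEF"), moa)
        assert len(out) == 12  # one contact and one oral row per compound
        for row in out.itertuples():
            value, tier = EXPECTED_TIERS[row.compound]
            assert row.ld50_ug_per_bee == pytest.approx(value), row.compound
            assert row.tier == tier, row.compound
            if tier <= 4:
                assert row.n_records >= 1

    def test_geometric_mean_keeps_duplicates(self):
        clean = standardize_and_filter(
            frame(rec("a", "oral", 2.0), rec("a", "oral", 2.0), rec("a", "oral", 8.0),
                  rec("a", "contact", 1.0)))
        out = consensus_table(clean, ["a"], {"a": "g"})
        oral = out[out["route"] == "oral"].iloc[0]
        assert oral.ld50_ug_per_bee == pytest.approx((2 * 2 * 8) ** (1 / 3))
        assert oral.n_records == 3

    def test_single_regulatory_greater_than_bound(self):
        clean = standardize_and_filter(
            frame(rec("a", "oral", 11.0, bound="greater_than"),
                  rec("a", "contact", 11.0, bound="greater_than")))
        out = consensus_table(clean, ["a"], {"a": "g"})
        assert (out["ld50_ug_per_bee"] == 11.0).all()
        assert (out["tier"] == 3).all()

    def test_less_than_bounds_take_precedence_over_greater_than(self):
        clean = standardize_and_filter(
            frame(rec("a", "oral", 3.0, bound="less_than"),
                  rec("a", "oral", 10.0, bound="greater_than"),
                  rec("a", "contact", 3.0, bound="less_than")))
        out = consensus_table(clean, ["a"], {"a": "g"})
        assert (out["ld50_ug_per_bee"] == 3.0).all()

    @pytest.mark.parametrize("compound", list("BCDEF"))
    def test_adding_a_regulatory_point_never_raises_the_tier(self, compound):
        records, moa = six_tier_fixture()
        clean = standardize_and_filter(records)
        before = consensus_table(clean, list("ABCDEF"), moa)
        extra = standardize_and_filter(
            frame(rec(compound, "oral", 1.0), rec(compound, "contact", 1.0)))
        after = consensus_table(pd.concat([clean, extra], ignore_index=True),
                                list("ABCDEF"), moa)
        for route in ("contact", "oral"):
            t0 = before.query("compound == @compound and route == @route")["tier"].iloc[0]
            t1 = after.query("compound == @compound and route == @route")["tier"].iloc[0]
            assert t1 <= t0
            assert t1 == 1

    def test_every_catalog_compound_gets_both_routes(self, clean_data):
        from beetox import default_scenario
        cfg = default_scenario(seed=0, p_missing_use=0.0, p_withheld=0.0)
        clean = standardize_and_filter(clean_data.toxicity)
        catalog = [c.compound_id for c in cfg.compounds]
        moa = {c.compound_id: c.moa_group for c in cfg.compounds}
        out = consensus_table(clean, catalog, moa)
        assert len(out) == 2 * len(catalog)
        assert (out["ld50_ug_per_bee"] > 0).all()
        assert out["tier"].isin(range(1, 7)).all()

    def test_empty_universe_is_an_explicit_failure(self):
        clean = standardize_and_filter(frame(rec("a", "oral", 1.0, life_stage="larva")))
        with pytest.raises(ConsensusError):
            consensus_table(clean, ["a"], {"a": "g"})

    def test_uncovered_moa_table_rejected(self):
        records, moa = six_tier_fixture()
        with pytest.raises(ValueError):
            consensus_table(standardize_and_filter(records), ["A", "Z"], moa)


class TestMoaMedians:
    def _consensus(self, values, group="g"):
        return pd.DataFrame({
            "compound": [f"c{i}" for i in range(len(values))],
            "route": "oral",
            "ld50_ug_per_bee": values,
            "tier": 1,
        }), {f"c{i}": group for i in range(len(values))}

    def test_odd_count_median(self):
        cons, moa = self._consensus([1.0, 10.0, 100.0])
        out = moa_median_table(cons, moa)
        assert out["median_ld50_ug_per_bee"].iloc[0] == 10.0

    def test_even_count_median_is_arithmetic_midpoint(self):
        cons, moa = self._consensus([1.0, 100.0])
        out = moa_median_table(cons, moa)
        assert out["median_ld50_ug_per_bee"].iloc[0] == 50.5

    def test_groups_without_members_absent(self):
        cons, moa = self._consensus([1.0, 2.0])
        moa["orphan"] = "empty-group"
        out = moa_median_table(cons, moa)
        assert set(out["moa_group"]) == {"g"}

    def test_rejects_fallback_tiers_in_input(self):
        cons, moa = self._consensus([1.0, 2.0])
        cons.loc[0, "tier"] = 5
        with pytest.raises(ValueError):
            moa_median_table(cons, moa)
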