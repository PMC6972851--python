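"""Extent/intensity decomposition: imputation, identities, aggregation."""

import numpy as np
import pandas as pd
import pytest

from beetox import (component_fold_changes, county_components, impute_census,
                    regional_summary)
from beetox.components import COMPONENT_MEASURES
from conftest import run_to_loads


def landuse_frame(rows):
    return pd.DataFrame(rows, columns=["fips", "year", "land_ha",
                                       "cropland_ha", "treated_ha"])


def loads_frame(rows):
    return pd.DataFrame(rows, columns=["fips", "year", "kg_total",
                                       "contact_load", "oral_load"])


class TestImputeCensus:
    def test_withheld_cell_gets_county_mean_of_other_years(self):
        lu = landuse_frame([("a", 1997, 1e4, 5e3, 100.0),
                            ("a", 2002, 1e4, 5e3, np.nan),
                            ("a", 2007, 1e4, 5e3, 120.0),
                            ("a", 2012, 1e4, 5e3, 140.0)])
        out = impute_census(lu)
        assert out.loc[1, "treated_ha"] == pytest.approx(120.0)
        assert bool(out.loc[1, "imputed_treated_ha"])

    def test_field_withheld_everywhere_becomes_zero(self):
        lu = landuse_frame([("a", y, 1e4, 5e3, np.nan)
                            for y in (1997, 2002, 2007, 2012)])
        out = impute_census(lu)
        assert (out["treated_ha"] == 0).all()

    def test_no_withheld_cells_is_identity(self):
        lu = landuse_frame([("a", 1997, 1e4, 5e3, 100.0),
                            ("a", 2002, 1e4, 6e3, 200.0)])
        out = impute_census(lu)
        pd.testing.assert_frame_equal(out[lu.columns], lu)
        assert not out["clamped"].any()

    def test_masked_cell_equal_to_mean_round_trips_exactly(self):
        # mask a cell whose value equals the mean of the county's other years
        truth = landuse_frame([("a", 1997, 1e4, 5e3, 100.0),
                               ("a", 2002, 1e4, 5e3, 120.0),
                               ("a", 2007, 1e4, 5e3, 140.0)])
        masked = truth.copy()
        masked.loc[1, "treated_ha"] = np.nan  # 120 == mean(100, 140)
        out = impute_census(masked)
        assert out.loc[1, "treated_ha"] == truth.loc[1, "treated_ha"]

    def test_imputation_overshoot_clamped_and_flagged(self):
        lu = landuse_frame([("a", 1997, 1e4, 200.0, 190.0),
                            ("a", 2002, 1e4, 50.0, np.nan),
                            ("a", 2007, 1e4, 300.0, 290.0)])
        out = impute_census(lu)
        assert out.loc[1, "treated_ha"] == out.loc[1, "cropland_ha"] == 50.0
        assert bool(out.loc[1, "clamped"])


class TestCountyComponents:
    def test_worked_example_treated_48_of_1000_ha(self):
        # 48 of 1000 ha treated, 720e9 oral doses: extent 4.8%, oral
        # intensity 15e9 per treated ha, oral load 0.72e9 per land ha
        loads = loads_frame([("a", 2012, 48.0, 240e9, 720e9)])
        lu = impute_census(landuse_frame([("a", 2012, 1000.0, 400.0, 48.0)]))
        out = county_components(loads, lu, [2012])
        row = out.iloc[0]
        assert row.extent_land == pytest.approx(0.048)
        assert row.intensity_oral == pytest.approx(15e9)
        assert row.load_per_ha_oral == pytest.approx(0.72e9)
        assert row.app_rate == pytest.approx(1.0)

    def test_zero_treated_area_flags_intensity_keeps_load_per_ha(self):
        loads = loads_frame([("a", 2012, 10.0, 5e9, 5e9)])
        lu = impute_census(landuse_frame([("a", 2012, 1000.0, 400.0, 0.0)]))
        out = county_components(loads, lu, [2012])
        row = out.iloc[0]
        assert bool(row.undefined_intensity)
        assert np.isnan(row.intensity_oral) and np.isnan(row.app_rate)
        assert row.load_per_ha_oral == pytest.approx(5e6)

    def test_unmatched_fips_excluded(self, caplog):
        loads = loads_frame([("a", 2012, 1.0, 1e9, 1e9),
                             ("ghost", 2012, 1.0, 1e9, 1e9)])
        lu = impute_census(landuse_frame([("a", 2012, 1000.0, 400.0, 48.0)]))
        with caplog.at_level("WARNING"):
            out = county_components(loads, lu, [2012])
        assert set(out["fips"]) == {"a"}
        assert "ghost" in caplog.text

    def test_multiplicative_identity_on_synthetic_counties(self, default_data):
        from beetox import default_scenario
        cfg = default_scenario(seed=0)
        _, loads = run_to_loads(cfg, default_data)
        lu = impute_census(default_data.landuse)
        comps = county_components(loads, lu, cfg.census_years)
        for route in ("contact", "oral"):
            product = (comps["cropland_frac"] * comps["prop_cropland_treated"]
                       * comps["app_rate"] * comps[f"potency_{route}"])
            lhs = comps[f"load_per_ha_{route}"]
            ok = product.notna() & lhs.notna() & (lhs > 0)
            assert ok.sum() > 300
            assert np.allclose(product[ok], lhs[ok], rtol=1e-9)


class TestRegionalSummary:
    def test_single_county_region_equals_county_row(self):
        loads = loads_frame([("a", 2012, 48.0, 240e9, 720e9)])
        lu = impute_census(landuse_frame([("a", 2012, 1000.0, 400.0, 48.0)]))
        comps = county_components(loads, lu, [2012])
        summary = regional_summary(comps, {"a": "R1"})
        r1 = summary[summary["region"] == "R1"].iloc[0]
        assert r1.extent_land == pytest.approx(comps.iloc[0].extent_land)
        assert r1.intensity_oral == pytest.approx(comps.iloc[0].intensity_oral)

    def test_sum_based_aggregation_matches_direct_oracle(self):
        rng = np.random.default_rng(4)
        rows_l, rows_u = [], []
        for i in range(3):
            land = rng.uniform(1e4, 1e5)
            crop = land * rng.uniform(0.2, 0.6)
            treated = crop * rng.uniform(0.05, 0.5)
            rows_u.append((f"c{i}", 2012, land, crop, treated))
            rows_l.append((f"c{i}", 2012, rng.uniform(10, 100),
                           rng.uniform(1e9, 1e11), rng.uniform(1e9, 1e11)))
        loads, lu = loads_frame(rows_l), impute_census(landuse_frame(rows_u))
        comps = county_components(loads, lu, [2012])
        summary = regional_summary(comps, {f"c{i}": "R" for i in range(3)})
        r = summary[summary["region"] == "R"].iloc[0]
        assert r.extent_land == pytest.approx(
            sum(u[4] for u in rows_u) / sum(u[2] for u in rows_u))
        assert r.intensity_oral == pytest.approx(
            sum(l[4] for l in rows_l) / sum(u[4] for u in rows_u))
        assert r.app_rate == pytest.approx(
            sum(l[2] for l in rows_l) / sum(u[4] for u in rows_u))

    def test_regions_sum_consistently_to_national_load(self, default_data):
        from beetox import default_scenario
        from beetox.synthetic import region_map
        cfg = default_scenario(seed=0)
        _, loads = run_to_loads(cfg, default_data)
        lu = impute_census(default_data.landuse)
        comps = county_components(loads, lu, cfg.census_years)
        summary = regional_summary(comps, region_map(default_data.counties))
        for year in cfg.census_years:
            g = summary[summary["year"] == year]
            nat = g[g["region"] == "Contiguous US"].iloc[0]
            reg = g[g["region"] != "Contiguous US"]
            total = (reg["load_per_ha_oral"] * reg["land_ha"]).sum()
            assert total == pytest.approx(nat.load_per_ha_oral * nat.land_ha, rel=1e-9)

    def test_unknown_region_label_is_an_error(self):
        loads = loads_frame([("a", 2012, 1.0, 1e9, 1e9)])
        lu = impute_census(landuse_frame([("a", 2012, 1000.0, 400.0, 48.0)]))
        comps = county_components(loads, lu, [2012])
        with pytest.raises(KeyError):
            regional_summary(comps, {"other-county": "R1"})


class TestComponentFoldChanges:
    def _comps(self, scale_2012):
        """Two census years; 2012 scaled per-measure by the given factors."""
        base = dict(land=1e4, crop=4e3, treated=1e3, kg=100.0,
                    contact=1e12, oral=2e12)
        rows_l = [("a", 1997, base["kg"], base["contact"], base["oral"]),
                  ("a", 2012, base["kg"] * scale_2012.get("kg", 1),
                   base["contact"] * scale_2012.get("contact", 1),
                   base["oral"] * scale_2012.get("oral", 1))]
        rows_u = [("a", 1997, base["land"], base["crop"], base["treated"]),
                  ("a", 2012, base["land"],
                   base["crop"] * scale_2012.get("crop", 1),
                   base["treated"] * scale_2012.get("treated", 1))]
        lu = impute_census(landuse_frame(rows_u))
        return county_components(loads_frame(rows_l), lu, [1997, 2012])

    def test_no_change_gives_unit_ratios(self):
        out = component_fold_changes(self._comps({}), 1997, 2012)
        assert np.allclose(out["fold_change"], 1.0)

    def test_ratio_definition(self):
        out = component_fold_changes(self._comps({"oral": 0.3}), 1997, 2012)
        oral = out[out["measure"] == "oral_load"].iloc[0]
        assert oral.fold_change == pytest.approx(0.3)  # a 70% decline

    def test_load_ratio_is_product_of_component_ratios(self):
        # oral potency x3 (load x3 at fixed kg), rate halved (kg x0.5 ->
        # load x0.5 too at fixed potency): net oral load ratio 1.5
        out = component_fold_changes(self._comps({"kg": 0.5, "oral": 1.5}),
                                     1997, 2012).set_index("measure")
        assert out.loc["app_rate", "fold_change"] == pytest.approx(0.5)
        assert out.loc["potency_oral", "fold_change"] == pytest.approx(3.0)
        assert out.loc["oral_load", "fold_change"] == pytest.approx(1.5)

    def test_zero_baseline_flagged_nan(self):
        comps = self._comps({})
        comps.loc[comps["year"] == 1997, "oral_load"] = 0.0
        comps.loc[comps["year"] == 1997, "potency_oral"] = 0.0
        out = component_fold_changes(comps, 1997, 2012).set_index("measure")
        assert np.isnan(out.loc["oral_load", "fold_change"])

    def test_reports_all_component_measures(self):
        out = component_fold_changes(self._comps({}), 1997, 2012)
        assert set(out["measure"]) == set(COMPONENT_MEASURES)
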