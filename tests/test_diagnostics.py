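"""Relative exploitation, annual series, core range, erosion labels."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spatstock import SurveyDataset
from spatstock.diagnostics import (
    DEFAULT_DELTA,
    ErosionTrajectory,
    annual_parameter_series,
    core_range_mask,
    erosion_classify,
    relative_exploitation,
)
from spatstock.diagnostics import _label_transition
from spatstock.errors import SchemaError


def _survey_with_zones(counts_by_zone_year):
    rows = []
    rng = np.random.default_rng(0)
    for (zone, year), total in counts_by_zone_year.items():
        # split the zone-year total over two sets
        a = total // 2
        rows.append((rng.uniform(0, 1), rng.uniform(0, 1), year, a, zone))
        rows.append((rng.uniform(0, 1), rng.uniform(0, 1), year, total - a, zone))
    return SurveyDataset(
        pd.DataFrame(rows, columns=["lon", "lat", "year", "count", "subzone"])
    )


class TestRelativeExploitation:
    def test_equal_shares_give_unity(self):
        survey = _survey_with_zones({("A", 1): 10, ("B", 1): 90})
        landings = pd.DataFrame(
            {"subzone": ["A", "B"], "year": [1, 1], "landings": [10.0, 90.0]}
        )
        table = relative_exploitation(landings, survey).df
        assert np.allclose(table["re"], 1.0)

    def test_ratio_of_shares(self):
        survey = _survey_with_zones({("A", 1): 25, ("B", 1): 75})
        landings = pd.DataFrame(
            {"subzone": ["A", "B"], "year": [1, 1], "landings": [50.0, 50.0]}
        )
        table = relative_exploitation(landings, survey).df.set_index("subzone")
        assert table.loc["A", "re"] == pytest.approx(2.0)
        assert table.loc["B", "re"] == pytest.approx(50 / 75, rel=1e-12)

    def test_three_zone_two_year_hand_table(self):
        """Spreadsheet-style oracle over a full small table."""
        counts = {("A", 1): 100, ("B", 1): 300, ("C", 1): 600,
                  ("A", 2): 50, ("B", 2): 50, ("C", 2): 100}
        land = {("A", 1): 20.0, ("B", 1): 30.0, ("C", 1): 50.0,
                ("A", 2): 60.0, ("B", 2): 30.0, ("C", 2): 10.0}
        survey = _survey_with_zones(counts)
        landings = pd.DataFrame(
            [(z, y, v) for (z, y), v in land.items()],
            columns=["subzone", "year", "landings"],
        )
        table = relative_exploitation(landings, survey).df
        for _, r in table.iterrows():
            z, y = r["subzone"], r["year"]
            land_share = land[(z, y)] / sum(v for (zz, yy), v in land.items() if yy == y)
            obis_share = counts[(z, y)] / sum(v for (zz, yy), v in counts.items() if yy == y)
            assert r["re"] == pytest.approx(land_share / obis_share, rel=1e-12)

    def test_share_conservation(self):
        survey = _survey_with_zones({("A", 1): 11, ("B", 1): 23, ("C", 1): 66})
        landings = pd.DataFrame(
            {"subzone": ["A", "B", "C"], "year": 1, "landings": [5.0, 25.0, 70.0]}
        )
        t = relative_exploitation(landings, survey).df
        assert (t["landings"] / t["landings_total"]).sum() == pytest.approx(1.0)
        assert (t["obis"] / t["obis_total"]).sum() == pytest.approx(1.0)

    def test_zero_survey_zone_flagged_undefined(self):
        survey = _survey_with_zones({("A", 1): 100, ("B", 1): 0})
        landings = pd.DataFrame(
            {"subzone": ["A", "B"], "year": [1, 1], "landings": [50.0, 50.0]}
        )
        table = relative_exploitation(landings, survey).df.set_index("subzone")
        assert math.isnan(table.loc["B", "re"])
        assert np.isfinite(table.loc["A", "re"])

    def test_zero_total_year_excluded_with_warning(self):
        survey = _survey_with_zones({("A", 1): 100, ("A", 2): 0})
        landings = pd.DataFrame(
            {"subzone": ["A", "A"], "year": [1, 2], "landings": [10.0, 10.0]}
        )
        with pytest.warns(UserWarning, match="excluded"):
            table = relative_exploitation(landings, survey)
        assert table.excluded_years == [2]

    def test_attach_to_survey_adds_covariate(self):
        survey = _survey_with_zones({("A", 1): 40, ("B", 1): 60})
        landings = pd.DataFrame(
            {"subzone": ["A", "B"], "year": [1, 1], "landings": [70.0, 30.0]}
        )
        table = relative_exploitation(landings, survey)
        joined = table.attach_to_survey(survey)
        assert "re" in joined.covariates
        assert np.isfinite(joined.df["re"]).all()

    def test_missing_columns_rejected(self):
        survey = _survey_with_zones({("A", 1): 5})
        with pytest.raises(SchemaError):
            relative_exploitation(pd.DataFrame({"year": [1]}), survey)


class TestAnnualSeries:
    def test_constant_field_recovers_range(self):
        """Annual spatial-only fits on years drawn from one stationary
        process recover the generating range within 30% at the median."""
        from shapely.geometry import box

        from spatstock.simulate import ScenarioConfig, simulate_survey

        cfg = ScenarioConfig(
            domain=box(0, 0, 1, 1), n_years=5, sets_per_year=150, rho=0.3, sigma=1.5,
            a=0.99, phi=1.0, intercept=2.0, temperature=False, seed=42,
            start_year=1990, mesh_max_edge=0.1,
        )
        data = simulate_survey(cfg)
        traj = annual_parameter_series(data, max_edge=0.16, cutoff=0.08, maxfev=60)
        ok = traj.valid()
        assert len(ok) == 5
        assert abs(np.median(ok["rho"]) - 0.3) / 0.3 < 0.3

    def test_sparse_year_flagged_not_dropped(self, small_survey):
        df = small_survey.df.copy()
        first = df["year"] == df["year"].min()
        thinned = pd.concat([df[first].head(3), df[~first]]).reset_index(drop=True)
        traj = annual_parameter_series(
            SurveyDataset(thinned), max_edge=0.25, maxfev=30, min_sets=10
        )
        row = traj.series.iloc[0]
        assert row["status"] == "too_few_sets"
        assert math.isnan(row["rho"])
        assert (traj.series["status"].iloc[1:] == "ok").all()


class TestCoreRange:
    def test_ordered_surface_masks_exact_quarter(self):
        surface = np.arange(1.0, 101.0).reshape(10, 10)
        mask = core_range_mask(surface, quantile=0.75)
        assert mask.mask.sum() == 25
        assert mask.masked_fraction == pytest.approx(0.25)

    def test_two_bumps_patches_and_separation(self):
        x = np.linspace(0, 3, 120)
        y = np.linspace(0, 1, 40)
        GX, GY = np.meshgrid(x, y)
        rho = 0.3
        surf = np.exp(-(((GX - 0.7) ** 2 + (GY - 0.5) ** 2) / 0.02)) + np.exp(
            -(((GX - 0.7 - 3 * rho) ** 2 + (GY - 0.5) ** 2) / 0.02)
        )
        mask = core_range_mask(surf, quantile=0.9, x=x, y=y, rho=rho)
        assert len(mask.patches) == 2
        sep = mask.separations.iloc[0]
        assert sep["separation_over_rho"] >= 2.0
        assert sep["separation"] == pytest.approx(3 * rho, abs=0.1)

    def test_contraction_keeps_maxima_and_shrinks_area(self):
        x = np.linspace(-1, 1, 80)
        GX, GY = np.meshgrid(x, x)
        r2 = GX**2 + GY**2
        year1 = 5.0 * np.exp(-((r2 / 0.3**2) ** 2))
        year2 = 5.0 * np.exp(-((r2 / 0.15**2) ** 2))
        masks = core_range_mask({1: year1, 2: year2}, quantile=0.75, x=x, y=x)
        m1, m2 = masks
        assert m2.mask.sum() < m1.mask.sum()
        assert m2.patches[0]["max_value"] == pytest.approx(m1.patches[0]["max_value"], rel=1e-3)
        assert m1.threshold == m2.threshold  # pooled by default

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(3)
        surf = rng.normal(size=(30, 30))
        sizes = [
            core_range_mask(surf, quantile=q).mask.sum() for q in (0.5, 0.65, 0.8, 0.95)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_degenerate_constant_surface(self):
        mask = core_range_mask(np.ones((5, 5)), quantile=0.75)
        assert mask.degenerate
        assert mask.mask.all()

    def test_nan_cells_stay_unmasked(self):
        surf = np.arange(1.0, 101.0).reshape(10, 10)
        surf[0, :] = np.nan
        mask = core_range_mask(surf, quantile=0.75)
        assert not mask.mask[0].any()


class TestErosionClassifier:
    def test_second_collapse_years_label_erosion(self):
        # rho 4.40 -> 26.43 with sigma 4.2 -> 2.1
        assert _label_transition(math.log(26.43 / 4.40), math.log(2.1 / 4.2),
                                 DEFAULT_DELTA, DEFAULT_DELTA) == "erosion"

    def test_first_collapse_years_label_erosion(self):
        # rho 2.61 -> 7.50 with sigma 2.8 -> 2.2
        assert _label_transition(math.log(7.50 / 2.61), math.log(2.2 / 2.8),
                                 DEFAULT_DELTA, DEFAULT_DELTA) == "erosion"

    def test_no_movement_is_fluctuation(self):
        assert _label_transition(0.0, 0.0, DEFAULT_DELTA, DEFAULT_DELTA) == "fluctuation"

    def test_recovery_is_mirror_of_erosion(self):
        assert _label_transition(math.log(4.40 / 26.43), math.log(4.2 / 2.1),
                                 DEFAULT_DELTA, DEFAULT_DELTA) == "recovery"

    @given(
        st.floats(-3, 3), st.floats(-3, 3),
        st.floats(0.1, 1.0), st.floats(0.1, 1.0),
    )
    def test_time_reversal_swaps_labels(self, dr, ds, d_rho, d_sigma):
        fwd = _label_transition(dr, ds, d_rho, d_sigma)
        rev = _label_transition(-dr, -ds, d_rho, d_sigma)
        swap = {"erosion": "recovery", "recovery": "erosion",
                "stable": "stable", "fluctuation": "fluctuation"}
        assert rev == swap[fwd]

    def test_trajectory_labelling_and_missing_years(self):
        series = pd.DataFrame(
            {
                "year": [1970, 1971, 1972, 1973],
                "rho": [3.1, 2.61, math.nan, 7.5],
                "sigma": [3.7, 2.8, math.nan, 2.2],
                "n_sets": 100,
                "status": ["ok", "ok", "failed", "ok"],
                "rho_exceeds_domain": False,
            }
        )
        labelled = erosion_classify(ErosionTrajectory(series=series))
        t = labelled.transitions
        assert list(t["label"][1:3]) == ["skipped", "skipped"]
        assert t["label"].iloc[0] in {"erosion", "stable", "fluctuation", "recovery"}

    def test_single_year_rejected(self):
        series = pd.DataFrame(
            {"year": [1970], "rho": [1.0], "sigma": [1.0], "n_sets": 10,
             "status": ["ok"], "rho_exceeds_domain": False}
        )
        with pytest.raises(ValueError):
            erosion_classify(ErosionTrajectory(series=series))


class TestCollapsePipeline:
    def test_direction_of_annual_estimates(self, collapse_study):
        """Across the engineered collapse the annual fits move toward
        larger rho and smaller sigma (flattened field) in most seeds."""
        directional = 0
        for r in collapse_study:
            s = r["series"]
            directional += (s["rho"].iloc[-1] > s["rho"].iloc[0]) and (
                s["sigma"].iloc[-1] < s["sigma"].iloc[0]
            )
        assert directional >= 16

    def test_sigma_always_collapses(self, collapse_study):
        drops = [r["series"]["sigma"].iloc[-1] < r["series"]["sigma"].iloc[0]
                 for r in collapse_study]
        assert sum(drops) >= 18
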