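"""Replicate/depth averaging, windowing, log transform, and scenario thinning."""

import numpy as np
import pandas as pd
import pytest

from trendpower import (
    GeneratorParams,
    ScenarioSpec,
    average_replicates,
    build_design_calendar,
    depth_average,
    exclude_project,
    mmp_post2015_design,
    prepare_series,
    prepare_table,
    simulate_measurements,
    standard_windows,
    subsample_scenario,
)
from trendpower.seasons import season_of

from conftest import OPEN_WINDOW


def obs_row(value, depth="surface", replicate=1, date="2016-03-01", site="S1",
            analyte="chl_a", project="AIMS"):
    return {
        "date": pd.Timestamp(date), "area": "A", "site": site,
        "project": project, "analyte": analyte, "depth": depth,
        "replicate": replicate, "value": value,
        "detection_limit": np.nan, "below_dl": 0,
    }


class TestAveraging:
    @pytest.mark.parametrize(
        "values,expected", [([1.0, 3.0], 2.0), ([2.0], 2.0), ([1.0, 2.0, 6.0], 3.0)]
    )
    def test_replicate_mean(self, values, expected):
        obs = pd.DataFrame(
            [obs_row(v, replicate=i + 1) for i, v in enumerate(values)]
        )
        out = average_replicates(obs)
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "layers,expected",
        [
            ([("surface", 2.0), ("bottom", 4.0)], 3.0),
            ([("surface", 2.0)], 2.0),
            ([("surface", 0.5), ("bottom", 0.5)], 0.5),
        ],
    )
    def test_depth_mean(self, layers, expected):
        obs = pd.DataFrame([obs_row(v, depth=d) for d, v in layers])
        out = depth_average(obs)
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(expected)

    def test_depth_average_rejects_unaveraged_replicates(self):
        obs = pd.DataFrame(
            [obs_row(1.0, replicate=1), obs_row(2.0, replicate=2)]
        )
        with pytest.raises(ValueError, match="average replicates first"):
            depth_average(obs)

    def test_averaging_order_invariant_on_balanced_data(self):
        """With balanced replicate counts, averaging replicates before or
        after depth-averaging yields the same values."""
        rng = np.random.default_rng(3)
        rows = []
        for date in ("2016-01-05", "2016-06-05"):
            for depth in ("surface", "bottom"):
                for rep in (1, 2):
                    rows.append(
                        obs_row(float(rng.lognormal()), depth=depth,
                                replicate=rep, date=date)
                    )
        obs = pd.DataFrame(rows)
        a = depth_average(average_replicates(obs))
        # alternate order: average depths within replicate, then replicates
        b = (
            obs.groupby(["area", "site", "project", "date", "analyte"],
                        as_index=False)["value"].mean()
        )
        merged = a.merge(b, on=["area", "site", "project", "date", "analyte"])
        np.testing.assert_allclose(merged["value_x"], merged["value_y"])


class TestExclusions:
    def test_nox_project_rows_removed(self):
        obs = pd.DataFrame(
            [
                obs_row(1.0, analyte="NOx", project="JCU"),
                obs_row(1.0, analyte="NOx", project="AIMS"),
                obs_row(1.0, analyte="chl_a", project="JCU"),
            ]
        )
        out = exclude_project(obs, "NOx", "JCU")
        assert len(out) == 2
        assert not ((out["analyte"] == "NOx") & (out["project"] == "JCU")).any()

    def test_unconfigured_analyte_untouched(self):
        obs = pd.DataFrame([obs_row(1.0, analyte="tss", project="JCU")])
        out = exclude_project(obs, "NOx", "JCU")
        pd.testing.assert_frame_equal(out, obs)


class TestWindows:
    def test_published_window_membership(self):
        w = standard_windows()
        dates = pd.Series(pd.to_datetime(["2009-06-01", "2016-01-01"]))
        assert w["pre-2015-S1"].contains(dates).tolist() == [True, False]
        assert w["post-2015"].contains(dates).tolist() == [False, True]

    def test_window_bounds_respect_inclusivity(self):
        w = standard_windows()
        edges = pd.Series(
            pd.to_datetime(
                ["2005-09-18", "2010-06-15", "2008-02-01", "2012-05-09", "2015-01-01"]
            )
        )
        assert not w["pre-2015-S1"].contains(edges).iloc[0]  # open left
        assert w["pre-2015-S2"].contains(edges).iloc[1]  # closed left
        assert w["pre-2015-S3"].contains(edges).iloc[2]  # closed both
        assert w["pre-2015-S3"].contains(edges).iloc[3]
        assert not w["post-2015"].contains(edges).iloc[4]  # open left

    def test_pre2015_window_spans(self):
        """S1 and S3 span roughly five years (1500-1600 days); S2's published
        bounds span 1661 days (its data coverage, not its bounds, matches the
        other two)."""
        w = standard_windows()
        assert 1500 <= w["pre-2015-S1"].span_days <= 1600
        assert 1500 <= w["pre-2015-S3"].span_days <= 1600
        assert w["pre-2015-S2"].span_days == 1661


class TestPrepareSeries:
    def test_log_transform_and_clocks(self):
        obs = pd.DataFrame(
            [obs_row(1.0, date="2016-02-01"), obs_row(2.0, date="2016-03-01")]
        )
        series = prepare_series(prepare_table(obs, exclusions=()), "chl_a", "A",
                                OPEN_WINDOW)
        assert series.data["log_value"].iloc[0] == pytest.approx(0.0)
        assert series.data["x_days"].tolist() == [0.0, 29.0]
        # clock runs from Jan 1 of the first sampling year
        assert series.data["clock_days"].iloc[0] == 31.0

    def test_nonpositive_value_rejected(self):
        obs = pd.DataFrame([obs_row(0.0)])
        with pytest.raises(ValueError, match="non-positive"):
            prepare_series(prepare_table(obs, exclusions=()), "chl_a", "A",
                           OPEN_WINDOW)

    def test_empty_window_rejected(self):
        obs = pd.DataFrame([obs_row(1.0, date="2016-03-01")])
        with pytest.raises(ValueError, match="no chl_a observations"):
            prepare_series(prepare_table(obs, exclusions=()), "chl_a", "A",
                           standard_windows()["pre-2015-S1"])


@pytest.fixture(scope="module")
def post2015_prepared():
    """Prepared post-2015 tables for one multi-group area (Burdekin)."""
    design = mmp_post2015_design()["Burdekin"]
    cal = build_design_calendar(design, seed=21)
    obs = simulate_measurements(
        cal, GeneratorParams(intercept=0.5, sigma=0.4, seed=22)
    )
    return prepare_table(obs, exclusions=())


class TestScenarioSubsampling:
    def test_labels_map_to_policies(self):
        assert ScenarioSpec("null").site_policy == "pre2015_sites"
        assert ScenarioSpec("null").frequency_policy == "pre2015_rate"
        assert ScenarioSpec("current").frequency_policy == "full_rate"
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioSpec("bogus")

    def test_current_is_identity(self, post2015_prepared):
        out = subsample_scenario(post2015_prepared, ScenarioSpec("current"))
        assert len(out) == len(post2015_prepared)

    @pytest.mark.filterwarnings("ignore:site .* has only")
    def test_null_restores_sparse_design(self, post2015_prepared):
        out = subsample_scenario(post2015_prepared, ScenarioSpec("null"))
        assert set(out["site"]) <= {"BUR1", "BUR2", "BUR4"}
        visits = out[["site", "date"]].drop_duplicates()
        visits["year"] = pd.to_datetime(visits["date"]).dt.year
        assert visits.groupby(["site", "year"]).size().le(3).all()
        # kept cadence is 1 wet + 2 dry in fully covered years
        visits["season"] = pd.to_datetime(visits["date"]).dt.month.map(season_of)
        full = visits[(visits.year > 2015) & (visits.year < 2019)]
        by = full.groupby(["site", "year", "season"]).size()
        assert by.xs("wet", level="season").le(1).all()
        assert by.xs("dry", level="season").le(2).all()

    @pytest.mark.filterwarnings("ignore:site .* has only")
    def test_null_plus_sites_keeps_all_sites_thinned(self, post2015_prepared):
        out = subsample_scenario(post2015_prepared, ScenarioSpec("null_plus_sites"))
        assert set(out["site"]) == set(post2015_prepared["site"])
        visits = out[["site", "date"]].drop_duplicates()
        visits["year"] = pd.to_datetime(visits["date"]).dt.year
        assert visits.groupby(["site", "year"]).size().le(3).all()

    @pytest.mark.filterwarnings("ignore:site .* has only")
    def test_subsampling_is_a_filter_and_nested(self, post2015_prepared):
        key = ["site", "date", "analyte"]
        rows = {
            label: set(
                map(
                    tuple,
                    subsample_scenario(post2015_prepared, ScenarioSpec(label))[
                        key
                    ].itertuples(index=False),
                )
            )
            for label in ("null", "null_plus_sites", "null_plus_samples", "current")
        }
        assert rows["null"] <= rows["null_plus_sites"]
        assert rows["null"] <= rows["null_plus_samples"]
        assert rows["null_plus_samples"] <= rows["current"]

    def test_sparse_site_year_warns_and_keeps_all(self):
        obs = pd.DataFrame(
            [obs_row(1.0, date="2016-02-01"), obs_row(1.2, date="2016-06-01",
                                                      site="S1")]
        )
        table = prepare_table(obs, exclusions=())
        table["site"] = "BUR1"  # a pre-2015 site so the site filter keeps it
        with pytest.warns(UserWarning, match="has only"):
            out = subsample_scenario(table, ScenarioSpec("null"))
        assert len(out) == len(table)
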