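"""Design matrix, OLS fit, robust trend tests, and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from trendpower import (
    ModelSpec,
    bh_fdr,
    build_design_matrix,
    durbin_watson,
    fit_ols,
    trend_test,
)
from trendpower.data_prep import PreparedSeries

from conftest import make_series


def series_from_frame(df) -> PreparedSeries:
    return PreparedSeries(df, analyte="chl_a", area="A", window_label="w")


class TestDesignMatrix:
    def test_harmonic_phase_at_january_first_and_half_period(self):
        s = make_series(n=10)
        s.data.loc[0, "clock_days"] = 0.0  # a sample on Jan 1
        s.data.loc[1, "clock_days"] = 365.25 / 2  # mid-year sample
        X = build_design_matrix(s)
        assert X["cos"].iloc[0] == pytest.approx(1.0)
        assert X["sin"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert X["cos"].iloc[1] == pytest.approx(-1.0)
        assert X["sin"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_single_site_single_project_columns(self):
        X = build_design_matrix(make_series(n=20))
        assert list(X.columns) == ["intercept", "x_days", "cos", "sin"]

    def test_indicator_columns_drop_reference_levels(self):
        s = make_series(n=30)
        s.data.loc[:, "site"] = np.where(np.arange(30) % 2, "S2", "S1")
        s.data.loc[:, "project"] = np.where(np.arange(30) % 3 == 0, "JCU", "AIMS")
        X = build_design_matrix(s)
        assert "site[S2]" in X.columns and "site[S1]" not in X.columns
        assert "project[JCU]" in X.columns and "project[AIMS]" not in X.columns

    def test_rank_deficiency_names_offenders(self):
        s = make_series(n=20)
        s.data.loc[:, "x_days"] = 0.0  # constant column aliases the intercept
        with pytest.raises(ValueError, match="x_days"):
            build_design_matrix(s)

    def test_higher_harmonic_orders(self):
        X = build_design_matrix(make_series(n=30), ModelSpec(harmonic_order=2))
        assert {"cos", "sin", "cos_2", "sin_2"} <= set(X.columns)


class TestFit:
    def test_perfect_line_is_interpolated(self):
        s = make_series(n=10, sigma=0.0, intercept=2.0, slope_per_day=0.5)
        fit = fit_ols(s, ModelSpec(include_season=False))
        assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["x_days"] == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_free_seasonal_recovery(self):
        s = make_series(
            n=40, sigma=0.0, intercept=1.3, slope_per_day=2e-4, seasonal=(0.4, -0.25)
        )
        fit = fit_ols(s)
        assert fit.coefficients["cos"] == pytest.approx(0.4, abs=1e-8)
        assert fit.coefficients["sin"] == pytest.approx(-0.25, abs=1e-8)

    def test_decomposition_and_residual_sum(self, small_series):
        fit = fit_ols(small_series)
        y = small_series.data["log_value"].to_numpy()
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-12)
        assert abs(fit.residuals.sum()) < 1e-9
        assert 0.0 <= fit.r_squared <= 1.0

    def test_fit_refused_when_underdetermined(self):
        s = make_series(n=4)
        with pytest.raises(ValueError, match="cannot fit"):
            fit_ols(s)

    def test_matches_normal_equations_oracle(self):
        """On a tiny two-column instance the fit equals the explicit
        normal-equations solution (X'X)^-1 X'y."""
        s = make_series(n=8, sigma=0.5, seed=2)
        fit = fit_ols(s, ModelSpec(include_season=False))
        X = np.column_stack([np.ones(8), s.data["x_days"]])
        y = s.data["log_value"].to_numpy()
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(
            fit.coefficients[["intercept", "x_days"]], beta, atol=1e-10
        )
        rss = ((y - X @ beta) ** 2).sum()
        assert fit.sigma2 == pytest.approx(rss / (8 - 2), rel=1e-10)

    def test_seasonal_amplitude_recovered_within_mc_error(self):
        """Amplitude sqrt(b2^2+b3^2) and phase of a known seasonal signal are
        recovered on average across simulated series."""
        amps = []
        for seed in range(40):
            s = make_series(n=80, sigma=0.3, seasonal=(0.3, -0.2), seed=seed)
            fit = fit_ols(s)
            amps.append(np.hypot(fit.coefficients["cos"], fit.coefficients["sin"]))
        true_amp = np.hypot(0.3, -0.2)
        se_mean = np.std(amps, ddof=1) / np.sqrt(len(amps))
        assert abs(np.mean(amps) - true_amp) < 3 * se_mean + 0.01


class TestTrendTest:
    def test_zero_slope_gives_p_one(self):
        # y chosen orthogonal to centred x: slope exactly 0, residuals not
        df = pd.DataFrame(
            {
                "date": pd.date_range("2016-01-01", periods=4, freq="30D"),
                "site": "S1",
                "project": "AIMS",
                "x_days": [0.0, 30.0, 60.0, 90.0],
                "clock_days": [0.0, 30.0, 60.0, 90.0],
                "log_value": [1.0, 2.0, 2.0, 1.0],
            }
        )
        fit = fit_ols(series_from_frame(df), ModelSpec(include_season=False))
        tt = trend_test(fit)
        assert tt.estimate == pytest.approx(0.0, abs=1e-14)
        assert tt.p_value == pytest.approx(1.0)
        assert not tt.significant

    def test_strong_trend_with_tiny_noise_always_significant(self):
        s = make_series(n=30, sigma=1e-8, slope_per_day=1e-3)
        tt = trend_test(fit_ols(s, ModelSpec(include_season=False)))
        assert tt.significant and tt.p_value < 1e-10

    def test_singleton_clusters_reproduce_hc_se(self, small_series):
        """The sandwich identity: cluster-robust SE with every row its own
        cluster equals the HC1 heteroskedasticity-robust SE."""
        fit = fit_ols(small_series)
        tt = trend_test(fit, se_type="cluster",
                        cluster_labels=np.arange(small_series.n))
        hc1 = fit._sm_result.HC1_se
        j = list(fit.coefficients.index).index("x_days")
        assert tt.se == pytest.approx(float(np.asarray(hc1)[j]), abs=1e-8)

    def test_cluster_needs_two_groups(self, small_series):
        fit = fit_ols(small_series)
        with pytest.raises(ValueError, match="at least 2 clusters"):
            trend_test(fit, se_type="cluster", cluster_labels=np.zeros(small_series.n))

    def test_hac_close_to_classical_under_iid(self, small_series):
        fit = fit_ols(small_series)
        classical = trend_test(fit, "classical")
        hac = trend_test(fit, "hac")
        assert hac.se == pytest.approx(classical.se, rel=0.5)

    def test_classical_size_under_null(self):
        """The classical trend test rejects a true null at close to the
        nominal 5% rate across simulated series."""
        rejections = 0
        n_sims = 500
        for seed in range(n_sims):
            s = make_series(n=30, sigma=0.5, seed=10_000 + seed)
            fit = fit_ols(s, ModelSpec(include_season=False))
            rejections += trend_test(fit).significant
        rate = rejections / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 2 * se + 0.005


class TestDiagnostics:
    def test_durbin_watson_alternating_residuals(self):
        dw, _ = durbin_watson(np.array([1.0, -1.0, 1.0, -1.0]))
        assert dw == pytest.approx(3.0)

    def test_durbin_watson_constant_residuals(self):
        dw, p = durbin_watson(np.array([1.0, 1.0, 1.0, 1.0]))
        assert dw == pytest.approx(0.0)
        assert p < 0.05  # strong positive autocorrelation signal

    def test_durbin_watson_iid_near_two(self):
        rng = np.random.default_rng(8)
        dw, p = durbin_watson(rng.normal(size=500))
        assert abs(dw - 2.0) < 0.2
        assert p > 0.05

    def test_durbin_watson_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(10))
        with pytest.raises(ValueError):
            durbin_watson(np.array([1.0, 2.0]))

    def test_bh_examples(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_bh_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_bh_adjusted_at_least_raw_and_bounded(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # step-up adjustment preserves the ranking of sorted p-values
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
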