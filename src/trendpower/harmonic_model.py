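"""Seasonal-trend regression with robust trend inference.

The working model for a log-transformed analyte series is ordinary least
squares with an intercept, institution (project) and sampling-location (site)
offsets, a linear trend in elapsed days, and an annual harmonic:

    y_i = b0 + b_p + b_s + b1 * x_i + b2 cos(2 pi xt_i / T) + b3 sin(2 pi xt_i / T) + e_i

with T = 365.25 days and the seasonal clock xt_i measured from January 1 of
the first sampling year, so the fitted seasonal curve is phased relative to
New Year. Errors are assumed uncorrelated with equal variance; departures are
handled at the inference step via HAC (Newey-West) or cluster-robust sandwich
covariances, and diagnosed with Durbin-Watson statistics under
Benjamini-Hochberg false-discovery-rate control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.stats.sandwich_covariance as sw
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

from .data_prep import PreparedSeries
from .synthetic_data import PERIOD_DAYS

TREND_COLUMN = "x_days"


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the seasonal-trend regression.

    ``harmonic_order`` adds cosine/sine pairs at multiples of the annual
    frequency; order 1 is the default (higher orders rarely improve fit for
    these analytes). ``include_season=False`` drops the harmonic entirely,
    giving a plain trend regression. Reference levels (omitted indicator
    columns) default to the alphabetically first site and project.
    """

    period_days: float = PERIOD_DAYS
    harmonic_order: int = 1
    include_season: bool = True
    include_project: bool = True
    include_sites: bool = True
    reference_site: str | None = None
    reference_project: str | None = None

    def __post_init__(self):
        if self.period_days <= 0:
            raise ValueError("period_days must be positive")
        if self.harmonic_order < 1:
            raise ValueError("harmonic_order must be at least 1")


@dataclass
class HarmonicFit:
    """A fitted seasonal-trend regression.

    Coefficients are on the natural-log scale; ``sigma2`` is the residual
    variance RSS/(n-p) and ``covariance`` the classical OLS covariance
    sigma2 * (X'X)^-1.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2: float
    n_obs: int
    df_resid: int
    r_squared: float
    design_matrix: pd.DataFrame = field(repr=False)
    series: PreparedSeries = field(repr=False)
    spec: ModelSpec = field(repr=False)
    _sm_result: object = field(default=None, repr=False)

    @property
    def trend(self) -> float:
        """Estimated trend slope (log units per day)."""
        return float(self.coefficients[TREND_COLUMN])

    def summary_table(self, alpha_fdr: float = 0.05) -> pd.DataFrame:
        """Per-term estimates, classical SEs, t and p values, with
        Benjamini-Hochberg adjusted p-values across terms."""
        se = np.sqrt(np.diag(self.covariance.to_numpy()))
        t = self.coefficients.to_numpy() / se
        p = 2 * st.t.sf(np.abs(t), self.df_resid)
        p_adj = bh_fdr(p)
        return pd.DataFrame(
            {
                "term": self.coefficients.index,
                "estimate": self.coefficients.to_numpy(),
                "se": se,
                "t": t,
                "p": p,
                "p_adjusted": p_adj,
                "significant_fdr": p_adj < alpha_fdr,
            }
        )


class TrendTest(NamedTuple):
    estimate: float
    se: float
    statistic: float
    p_value: float
    significant: bool
    se_type: str


def build_design_matrix(
    series: PreparedSeries, spec: ModelSpec = ModelSpec()
) -> pd.DataFrame:
    """Assemble the regression design matrix with labelled columns.

    Columns: intercept, project indicators (reference level omitted), site
    indicators (reference omitted; dropped entirely for single-site series),
    elapsed days, then cos/sin pairs per harmonic order. Indicator levels
    absent from the data are never materialised; the result must be full
    column rank or the offending columns are reported.
    """
    df = series.data
    if df.empty:
        raise ValueError("empty series")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}

    def add_indicators(values: pd.Series, prefix: str, reference: str | None):
        levels = sorted(values.unique())
        ref = reference if reference in levels else levels[0]
        for lev in levels:
            if lev != ref:
                cols[f"{prefix}[{lev}]"] = (values == lev).to_numpy(float)

    if spec.include_project:
        add_indicators(df["project"], "project", spec.reference_project)
    if spec.include_sites:
        add_indicators(df["site"], "site", spec.reference_site)
    cols[TREND_COLUMN] = df[TREND_COLUMN].to_numpy(float)
    if spec.include_season:
        omega = 2 * np.pi * df["clock_days"].to_numpy(float) / spec.period_days
        for k in range(1, spec.harmonic_order + 1):
            suffix = "" if k == 1 else f"_{k}"
            cols[f"cos{suffix}"] = np.cos(k * omega)
            cols[f"sin{suffix}"] = np.sin(k * omega)

    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by greedy rank check
        keep: list[str] = []
        bad: list[str] = []
        for c in X.columns:
            trial = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
            else:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {bad}")
    return X


def fit_ols(series: PreparedSeries, spec: ModelSpec = ModelSpec()) -> HarmonicFit:
    """Fit the seasonal-trend regression by ordinary least squares."""
    X = build_design_matrix(series, spec)
    y = series.data["log_value"].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"cannot fit {p} coefficients to {n} observations")
    res = sm.OLS(y, X).fit()
    return HarmonicFit(
        coefficients=pd.Series(res.params, index=X.columns),
        covariance=pd.DataFrame(
            res.cov_params(), index=X.columns, columns=X.columns
        ),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        sigma2=float(res.mse_resid),
        n_obs=n,
        df_resid=int(res.df_resid),
        r_squared=float(res.rsquared),
        design_matrix=X,
        series=series,
        spec=spec,
        _sm_result=res,
    )


def newey_west_lags(n: int) -> int:
    """Automatic Newey-West truncation lag, floor(4 (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


def trend_test(
    fit: HarmonicFit,
    se_type: str = "classical",
    cluster_labels: Sequence | None = None,
    alpha: float = 0.05,
) -> TrendTest:
    """Two-sided t-test of a zero trend slope.

    ``se_type`` selects the covariance estimator: ``classical`` (homoskedastic
    OLS), ``hac`` (Newey-West/Bartlett sandwich with automatic lag choice), or
    ``cluster`` (sandwich grouped by ``cluster_labels``, defaulting to the
    site, allowing arbitrary within-site correlation; the finite-cluster
    correction G/(G-1) * (n-1)/(n-p) is applied). Degrees of freedom are
    n - p for classical/HAC and G - 1 for clustered inference.
    """
    j = list(fit.coefficients.index).index(TREND_COLUMN)
    est = fit.trend
    res = fit._sm_result
    n, p_cols = fit.n_obs, len(fit.coefficients)
    if se_type == "classical":
        se = float(np.sqrt(fit.covariance.iloc[j, j]))
        df = fit.df_resid
    elif se_type == "hac":
        if cluster_labels is not None:
            raise ValueError("cluster_labels only apply to se_type='cluster'")
        cov = sw.cov_hac_simple(
            res, nlags=newey_west_lags(n), use_correction=True
        )
        se = float(np.sqrt(cov[j, j]))
        df = fit.df_resid
    elif se_type == "cluster":
        if cluster_labels is None:
            cluster_labels = fit.series.data["site"].to_numpy()
        _, groups = np.unique(np.asarray(cluster_labels), return_inverse=True)
        n_groups = int(groups.max()) + 1
        if n_groups < 2:
            raise ValueError("cluster-robust inference needs at least 2 clusters")
        cov = sw.cov_cluster(res, groups, use_correction=True)
        se = float(np.sqrt(cov[j, j]))
        df = n_groups - 1
    else:
        raise ValueError(f"unknown se_type {se_type!r}")
    tstat = est / se
    p = float(2 * st.t.sf(abs(tstat), df))
    return TrendTest(est, se, tstat, p, p < alpha, se_type)


def durbin_watson(residuals: np.ndarray) -> tuple[float, float]:
    """Durbin-Watson statistic and a normal-approximation p-value.

    The statistic is sum of squared successive differences over the residual
    sum of squares, in [0, 4] with expectation near 2 under independence. The
    p-value tests the null of no AR(1) autocorrelation using the large-sample
    approximation DW ~ N(2, 4/n), adequate for screening many series.
    """
    e = np.asarray(residuals, float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.all(e == 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    dw = float(_sm_durbin_watson(e))
    z = (dw - 2.0) / np.sqrt(4.0 / e.size)
    p = float(2 * st.norm.sf(abs(z)))
    return dw, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
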