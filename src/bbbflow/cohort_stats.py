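"""Cohort-level association statistics.

Descriptive normality (skewness/excess kurtosis), Pearson correlation,
simple linear regression with t-based 95% confidence intervals,
covariate adjustment by residualization, shared variance by principal
component analysis on the correlation matrix, and intraclass correlation
for interrater reliability. Significance is a two-sided p < 0.05 with no
multiple-comparison correction by default (a Bonferroni/FDR helper exists
but is opt-in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DescribeResult",
    "RegressionResult",
    "describe",
    "pearson",
    "simple_regression",
    "residualize",
    "shared_variance_pca",
    "icc",
    "adjust_pvalues",
]

ALPHA = 0.05


@dataclass
class DescribeResult:
    mean: float
    sd: float
    skewness: float
    kurtosis: float  # excess kurtosis (normal -> 0)
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False  # constant sample: skew/kurtosis undefined


@dataclass
class RegressionResult:
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    r: float
    n: int
    intercept: float
    residuals: np.ndarray

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def describe(values) -> DescribeResult:
    """Sample mean, SD, skewness, excess kurtosis and 95% CI of the mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("describe requires n >= 3")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return DescribeResult(mean, 0.0, float("nan"), float("nan"), mean, mean, n, True)
    tcrit = stats.t.ppf(1 - ALPHA / 2, n - 1)
    half = tcrit * sd / np.sqrt(n)
    return DescribeResult(
        mean=mean,
        sd=sd,
        skewness=float(stats.skew(x, bias=False)),
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=False)),
        ci_low=mean - half,
        ci_high=mean + half,
        n=n,
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input to correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def simple_regression(y, x) -> RegressionResult:
    """OLS of y on x with a t-based 95% CI and two-sided p for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - ALPHA / 2, n - 2)
    resid = y - (res.intercept + res.slope * x)
    return RegressionResult(
        beta=float(res.slope),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        p_value=float(res.pvalue),
        r=float(res.rvalue),
        n=n,
        intercept=float(res.intercept),
        residuals=resid,
    )


def residualize(values, covariates) -> np.ndarray:
    """Adjust for covariates: residuals of OLS of values on [1, covariates].

    The residuals have exactly zero mean and zero sample correlation with
    every covariate; residualizing is an orthogonal projection, hence
    idempotent. Sex or other categoricals must be pre-coded numerically.
    """
    y = np.asarray(values, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if n <= k + 1:
        raise ValueError("need more observations than covariates + 1")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def shared_variance_pca(region_matrix) -> dict:
    """Shared-variance summary of a (subjects x regions) matrix.

    PCA on the correlation matrix (columns standardized): returns the first
    principal component's variance share lambda_1 / sum(lambda) together
    with the mean +/- SD of the off-diagonal between-region correlations.
    """
    x = np.asarray(region_matrix, dtype=float)
    n, p = x.shape
    if p < 2 or n < 3:
        raise ValueError("need >= 2 regions and >= 3 subjects")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant region column")
    corr = np.corrcoef(x, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    off = corr[~np.eye(p, dtype=bool)]
    return {
        "first_pc_share": float(eig[0] / eig.sum()),
        "eigenvalues": eig,
        "corr_mean": float(off.mean()),
        "corr_sd": float(off.std(ddof=1)),
        "corr_min": float(off.min()),
        "corr_max": float(off.max()),
    }


def icc(ratings) -> float:
    """Two-way random, absolute-agreement, single-measure ICC — ICC(2,1).

    ``ratings`` is (subjects x raters), complete. From the mean-squares
    decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the residual
    mean square.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects-by-raters matrix")
    n, k = x.shape
    if k < 2 or n < 5:
        raise ValueError("icc requires >= 2 raters and >= 5 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix must be complete")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ssr = k * np.sum((subj_means - grand) ** 2)
    ssc = n * np.sum((rater_means - grand) ** 2)
    sse = np.sum((x - subj_means[:, None] - rater_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0  # identical, constant-free agreement
    return float((msr - mse) / denom)


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Optional multiple-comparison adjustment (off by default everywhere)."""
    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]
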