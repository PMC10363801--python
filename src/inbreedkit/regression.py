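"""Inbreeding-depression inference.

The inbreeding-depression rate (ID) is the slope of the ordinary
least-squares regression of log phenotype on the inbreeding coefficient F:

    log(y_i) = a + b F_i + e_i,        ID = b  (negative under depression).

Significance is assessed three ways: the parametric two-sided t-test of the
slope; a bootstrap over individuals (percentile CI, with one-sided
significance taken as the fraction of resampled slopes >= 0); and a
randomization test in which phenotypes are permuted among individuals and
the one-sided p-value is (N_more_depression + 1) / (n_perm + 1), counting
permuted slopes more negative than the observed one.

With exactly two F groups the OLS slope reduces to the difference of group
means of log phenotype over the F difference, which ties it to the
ratio-of-means estimator ID = log(mean_0 / mean_1) / dF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RegressionResult",
    "InbreedingDepressionRegression",
    "id_regression",
    "ratio_id",
    "permutation_test",
    "bootstrap_test",
    "correlations",
]


@dataclass(frozen=True)
class RegressionResult:
    """ID slope with its uncertainty measures."""

    slope: float
    intercept: float
    se: float
    p_parametric: float
    n: int
    p_bootstrap: float | None = None
    p_bootstrap_two_sided: float | None = None
    ci_bootstrap: tuple[float, float] | None = None
    p_permutation: float | None = None


def _ols(f: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, slope SE and two-sided parametric p."""
    n = f.size
    fc = f - f.mean()
    ssf = float(fc @ fc)
    if ssf == 0.0:
        raise ValueError("F values are constant; slope undefined")
    slope = float(fc @ (y - y.mean())) / ssf
    intercept = float(y.mean() - slope * f.mean())
    if n < 3:
        return slope, intercept, math.nan, math.nan
    resid = y - intercept - slope * f
    s2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(s2 / ssf)
    if se == 0.0:
        p = 0.0 if slope != 0.0 else 1.0
    else:
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return slope, intercept, se, p


class InbreedingDepressionRegression(RegressorMixin, BaseEstimator):
    """OLS regression of log phenotype on F with resampling inference.

    Parameters
    ----------
    n_boot, n_perm
        Number of bootstrap and permutation resamples (0 disables either).
    random_state
        Seed for the resampling generators.

    Attributes (after ``fit(F, log_y)``)
    ----------
    slope_, intercept_, se_ : OLS estimates; ``slope_`` is the ID rate.
    p_parametric_ : two-sided t-test p-value of the slope.
    p_permutation_ : one-sided randomization p for depression,
        (N_{slope* < slope_obs} + 1) / (n_perm + 1).
    p_bootstrap_ : fraction of bootstrap slopes >= 0 (one-sided for
        depression); ``p_bootstrap_two_sided_`` doubles the smaller tail.
    ci_bootstrap_ : 95% percentile interval of the bootstrap slopes.
    """

    def __init__(self, n_boot: int = 10_000, n_perm: int = 10_000, random_state=None):
        self.n_boot = n_boot
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        f = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if f.size != y.size:
            raise ValueError("F and phenotype vectors differ in length")
        if f.size < 2 or np.unique(f).size < 2:
            raise ValueError("need >= 2 observations with distinct F values")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in input (log of zero phenotype?)")
        self.slope_, self.intercept_, self.se_, self.p_parametric_ = _ols(f, y)
        self.n_ = int(f.size)
        rng = np.random.default_rng(self.random_state)
        if self.n_perm:
            self.p_permutation_ = _permutation_p(f, y, self.slope_, self.n_perm, rng)
        else:
            self.p_permutation_ = None
        if self.n_boot:
            (
                self.p_bootstrap_,
                self.p_bootstrap_two_sided_,
                self.ci_bootstrap_,
                self.n_boot_degenerate_,
            ) = _bootstrap(f, y, self.n_boot, rng)
        else:
            self.p_bootstrap_ = self.p_bootstrap_two_sided_ = None
            self.ci_bootstrap_ = None
            self.n_boot_degenerate_ = 0
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        f = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * f

    @property
    def result_(self) -> RegressionResult:
        check_is_fitted(self, "slope_")
        return RegressionResult(
            slope=self.slope_,
            intercept=self.intercept_,
            se=self.se_,
            p_parametric=self.p_parametric_,
            n=self.n_,
            p_bootstrap=self.p_bootstrap_,
            p_bootstrap_two_sided=self.p_bootstrap_two_sided_,
            ci_bootstrap=self.ci_bootstrap_,
            p_permutation=self.p_permutation_,
        )


def _slopes_for_y_matrix(f: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS slopes of every row of Y on the shared predictor f (vectorised)."""
    fc = f - f.mean()
    ssf = float(fc @ fc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    return (Yc @ fc) / ssf


def _permutation_p(
    f: np.ndarray, y: np.ndarray, observed: float, n_perm: int, rng: np.random.Generator
) -> float:
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    perm = np.empty((n_perm, y.size))
    for i in range(n_perm):
        perm[i] = rng.permutation(y)
    slopes = _slopes_for_y_matrix(f, perm)
    n_more = int(np.sum(slopes < observed))
    return (n_more + 1) / (n_perm + 1)


def _bootstrap(
    f: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
):
    n = y.size
    slopes = np.empty(n_boot)
    kept = 0
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fb = f[idx]
        if np.all(fb == fb[0]):
            degenerate += 1
            continue
        fc = fb - fb.mean()
        yb = y[idx]
        slopes[kept] = float(fc @ (yb - yb.mean())) / float(fc @ fc)
        kept += 1
    if kept == 0:
        raise ValueError("all bootstrap resamples degenerate (constant F)")
    slopes = slopes[:kept]
    p_ge0 = float(np.mean(slopes >= 0.0))
    p_two = 2.0 * min(p_ge0, float(np.mean(slopes <= 0.0)))
    p_two = min(p_two, 1.0)
    ci = (float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5)))
    return p_ge0, p_two, ci, degenerate


def id_regression(
    f_values,
    log_phenotypes,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed=None,
) -> RegressionResult:
    """Fit the ID regression and return the full result record."""
    est = InbreedingDepressionRegression(
        n_boot=n_boot, n_perm=n_perm, random_state=seed
    ).fit(f_values, log_phenotypes)
    return est.result_


def ratio_id(mean_noninbred: float, mean_inbred: float, delta_f: float) -> float:
    """Ratio-of-means ID estimate: log(mean_0 / mean_dF) / dF.

    Positive output denotes depression (mean declines with F), matching the
    convention in which a rate of e.g. 2.6 means a ~2.6% decline of the mean
    per 0.01 of inbreeding.
    """
    if mean_noninbred <= 0 or mean_inbred <= 0:
        raise ValueError("phenotype means must be positive")
    if delta_f <= 0:
        raise ValueError("delta_f must be positive")
    return math.log(mean_noninbred / mean_inbred) / delta_f


def permutation_test(f_values, log_phenotypes, n_perm: int = 10_000, seed=None) -> float:
    """One-sided randomization p-value for inbreeding depression."""
    f = np.asarray(f_values, dtype=float).reshape(-1)
    y = np.asarray(log_phenotypes, dtype=float).reshape(-1)
    observed, *_ = _ols(f, y)
    rng = np.random.default_rng(seed)
    return _permutation_p(f, y, observed, n_perm, rng)


def bootstrap_test(f_values, log_phenotypes, n_boot: int = 10_000, seed=None):
    """Bootstrap over individuals: (one-sided p, two-sided p, 95% CI)."""
    f = np.asarray(f_values, dtype=float).reshape(-1)
    y = np.asarray(log_phenotypes, dtype=float).reshape(-1)
    if f.size < 3:
        raise ValueError("bootstrap needs n >= 3")
    rng = np.random.default_rng(seed)
    p1, p2, ci, _ = _bootstrap(f, y, n_boot, rng)
    return p1, p2, ci


def correlations(table) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlations with two-sided p-values.

    ``table`` is an (n, k) array or DataFrame of paired complete
    observations; returns (r, p) as (k, k) arrays.
    """
    A = np.asarray(table, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a 2-D table of observations x variables")
    if not np.all(np.isfinite(A)):
        raise ValueError("correlations require complete observations")
    k = A.shape[1]
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(A[:, i], A[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return r, p
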