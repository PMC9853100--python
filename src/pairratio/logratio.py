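"""Log-ratio transformation benchmark tests for taxon pairs.

These are the transformation-based comparators to the beta-binomial pair
model: the counts of a pair are turned into Y'_i = log(Y_ia / Y_ib) after a
zero policy, and the group difference gamma_1 in E[Y'] = gamma_0 +
gamma_1 x_i is tested with a linear model (lrlm), a Wilcoxon rank-sum test
(lrw) or a label-permutation test (lrp). gamma_1 is the empirical,
transformation-based analogue of the log odds ratio of the beta-binomial
model.

Zero policies:

impute
    add the pseudocount to every zero count, keep all samples (default 1,
    the field-standard ad hoc choice);
drop_double
    remove samples where both counts are zero, impute remaining single
    zeros;
drop_any
    remove every zero-containing sample, no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .betabin import PairData, TestResult
from .errors import DesignError, DomainError, NoDataError

__all__ = ["LogRatioSample", "log_ratio_transform", "lrlm_test", "lrw_test", "lrp_test"]

ZERO_POLICIES = ("impute", "drop_double", "drop_any")


@dataclass
class LogRatioSample:
    """Transformed pair data: Y'_i with per-sample inclusion flags.

    ``y_prime`` has one entry per original sample and is NaN exactly where
    ``included`` is False — excluded samples are flagged, never silently
    dropped.
    """

    y_prime: np.ndarray
    design: pd.DataFrame
    included: np.ndarray
    zero_policy: str
    pseudocount: float

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def values(self) -> np.ndarray:
        return self.y_prime[self.included]

    def groups(self, column: str = "treatment") -> np.ndarray:
        return np.asarray(self.design[column])[self.included]


def log_ratio_transform(
    data: PairData, zero_policy: str = "impute", pseudocount: float = 1.0
) -> LogRatioSample:
    """Apply a zero policy and the pairwise log-ratio transform."""
    if zero_policy not in ZERO_POLICIES:
        raise DomainError(f"unknown zero policy {zero_policy!r}; choose from {ZERO_POLICIES}")
    ya = data.numerator_counts.astype(float)
    yb = data.denominator_counts.astype(float)

    if zero_policy == "impute":
        included = np.ones(len(ya), dtype=bool)
    elif zero_policy == "drop_double":
        included = ~((ya == 0) & (yb == 0))
    else:  # drop_any
        included = (ya > 0) & (yb > 0)
    if not included.any():
        raise NoDataError(f"zero policy {zero_policy!r} removed every sample")

    if zero_policy in ("impute", "drop_double"):
        ya = np.where(ya == 0, pseudocount, ya)
        yb = np.where(yb == 0, pseudocount, yb)
    y_prime = np.full(len(ya), np.nan)
    y_prime[included] = np.log(ya[included] / yb[included])
    return LogRatioSample(
        y_prime=y_prime,
        design=data.design,
        included=included,
        zero_policy=zero_policy,
        pseudocount=pseudocount,
    )


def _ols_wald(X: np.ndarray, y: np.ndarray, coef_idx: int) -> tuple[float, float, float, int]:
    """Closed-form OLS with a Wald t-test on one coefficient.

    Returns (estimate, se, t statistic, residual df). Kept free of model
    objects because it runs inside the simulation loops; agreement with
    statsmodels OLS is asserted in the test suite.
    """
    n, p = X.shape
    if n <= p:
        raise DesignError("not enough samples for the linear model")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise DesignError("degenerate design in linear model") from exc
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * XtX_inv[coef_idx, coef_idx]))
    est = float(beta[coef_idx])
    tstat = est / se if se > 0 else 0.0
    return est, se, tstat, df


def lrlm_test(
    samples: LogRatioSample,
    covariates: Sequence[str] = ("treatment",),
    group_col: str = "treatment",
    method_tag: str = "lrlm",
) -> TestResult:
    """Linear model on Y' with a Wald t-test on the group coefficient.

    With only the intercept and the group indicator this is algebraically
    the classic equal-variance two-sample t-test. A study covariate may be
    added for two-study designs.
    """
    covariates = list(covariates)
    if group_col not in covariates:
        raise DesignError(f"group column {group_col!r} must be among the covariates")
    y = samples.values()
    if len(y) < 3:
        raise NoDataError("need at least 3 included samples for the linear model")
    design = samples.design.loc[samples.included, covariates]
    g = np.asarray(design[group_col])
    if len(np.unique(g)) < 2:
        raise DesignError("both groups must be represented among included samples")
    X = np.column_stack([np.ones(len(y))] + [np.asarray(design[c], dtype=float) for c in covariates])
    coef_idx = 1 + covariates.index(group_col)
    est, se, tstat, df = _ols_wald(X, y, coef_idx)
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    tq = float(stats.t.ppf(0.975, df))
    return TestResult(
        statistic=tstat, df=df, p_value=p, estimate=est,
        ci_low=est - tq * se, ci_high=est + tq * se, method_tag=method_tag,
    )


def lrw_test(
    samples: LogRatioSample, group_col: str = "treatment", method_tag: str = "lrw"
) -> TestResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test on Y'.

    Exact enumeration when both groups have at most 10 samples and the data
    are tie-free; otherwise the normal approximation with tie and
    continuity corrections. No covariate adjustment.
    """
    y = samples.values()
    g = samples.groups(group_col)
    levels = np.unique(g)
    if len(levels) != 2:
        raise DesignError("rank-sum test requires exactly two represented groups")
    y0, y1 = y[g == levels[0]], y[g == levels[1]]
    if len(y0) == 0 or len(y1) == 0:
        raise DesignError("a group is empty")
    if np.all(y == y[0]):
        # all values identical: no evidence either way
        return TestResult(statistic=len(y0) * len(y1) / 2.0, df=np.nan, p_value=1.0,
                          method_tag=method_tag)
    tie_free = len(np.unique(y)) == len(y)
    method = "exact" if (tie_free and len(y0) <= 10 and len(y1) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(y0, y1, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(statistic=float(res.statistic), df=np.nan,
                      p_value=float(min(res.pvalue, 1.0)), method_tag=method_tag)


def lrp_test(
    samples: LogRatioSample,
    group_col: str = "treatment",
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = 0,
    method_tag: str = "lrp",
) -> TestResult:
    """Permutation test on the difference of group means of Y'.

    Group labels are permuted ``n_perm`` times (globally, ignoring any study
    structure) and the two-sided p-value uses the add-one estimator
    (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1), so p is never zero.
    """
    if n_perm < 1:
        raise DomainError("n_perm must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = samples.values()
    g = samples.groups(group_col)
    levels = np.unique(g)
    if len(levels) != 2:
        raise DesignError("permutation test requires exactly two represented groups")
    sel = g == levels[1]
    n1, n0 = int(sel.sum()), int((~sel).sum())
    total = float(y.sum())
    obs = float(y[sel].mean() - y[~sel].mean())

    # permuted mean difference depends only on the sum over the treated
    # subset; permute rows of a tiled matrix and contract with the indicator
    tiled = np.broadcast_to(y, (n_perm, len(y))).copy()
    rng.permuted(tiled, axis=1, out=tiled)
    sums1 = tiled[:, :n1].sum(axis=1)
    perm_stats = sums1 / n1 - (total - sums1) / n0
    n_extreme = int(np.sum(np.abs(perm_stats) >= abs(obs) - 1e-12))
    p = (1.0 + n_extreme) / (n_perm + 1.0)
    return TestResult(statistic=obs, df=np.nan, p_value=float(p), estimate=obs,
                      method_tag=method_tag)


def exhaustive_permutation_p(y: np.ndarray, g: np.ndarray) -> float:
    """Exact permutation p-value by full enumeration of group assignments.

    Exponential in n; intended for small instances and as an oracle for
    :func:`lrp_test`.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    levels = np.unique(g)
    idx1 = np.flatnonzero(g == levels[1])
    n, n1 = len(y), len(idx1)
    n0 = n - n1
    obs = abs(y[g == levels[1]].mean() - y[g == levels[0]].mean())
    total = y.sum()
    count = 0
    n_splits = 0
    for comb in combinations(range(n), n1):
        s1 = y[list(comb)].sum()
        stat = abs(s1 / n1 - (total - s1) / n0)
        if stat >= obs - 1e-12:
            count += 1
        n_splits += 1
    return count / n_splits
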