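"""Beta-binomial regression on taxon-pair counts.

The model for one taxon pair (a, b) observed in samples i = 1..n is

    Y_ia | (P_i, T_iab) ~ Binomial(T_iab, P_i),
    P_i ~ Beta(alpha1_i, alpha2_i),

where T_iab = Y_ia + Y_ib is the pairwise total. The latent beta law has
mean mu_i = alpha1_i / (alpha1_i + alpha2_i) and dispersion
theta = 1 / (alpha1_i + alpha2_i); the extra-binomial correlation is
phi = theta / (1 + theta). The mean is modelled on the logit scale with a
linear predictor, logit(mu_i) = x_i' beta, so for a two-group design
exp(beta_1) is the odds ratio of taxon a versus taxon b between groups.

Dispersion is intercept-only (one theta per pair) and is estimated jointly
with beta by maximum likelihood; the optimizer works on eta = logit(phi),
which equals log(theta), keeping the dispersion parameter unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import DesignError, DomainError, NoInformationError

__all__ = [
    "PairData",
    "BetaBinomialParams",
    "BetaBinomialFit",
    "TestResult",
    "betabin_logpmf",
    "betabin_proportion_variance",
    "fit_betabin",
    "lrt_group_effect",
    "wald_ci",
]

# Below this dispersion the beta-binomial is numerically indistinguishable
# from the binomial and the lgamma differences lose precision, so we switch
# to the exact binomial limit.
_THETA_BINOMIAL_LIMIT = 1e-6

# Optimizer box: |beta_j| <= 30 (odds ratios beyond e±30 are boundary
# estimates in practice) and theta in [1e-6, 1e4].
_BETA_BOUND = 30.0
_ETA_BOUNDS = (np.log(1e-6), np.log(1e4))

_MU_EPS = 1e-12


@dataclass
class PairData:
    """Counts and covariates for one taxon pair.

    ``numerator_counts[i]`` is Y_ia, ``pair_totals[i]`` is T_iab; the
    denominator count Y_ib = T_iab - Y_ia is implicit. ``design`` holds one
    row per sample with covariate columns (e.g. a 0/1 ``treatment``
    indicator and an optional 0/1 ``study`` indicator).
    """

    numerator_counts: np.ndarray
    pair_totals: np.ndarray
    design: pd.DataFrame
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.numerator_counts = np.asarray(self.numerator_counts)
        self.pair_totals = np.asarray(self.pair_totals)
        n = self.numerator_counts.shape[0]
        if self.pair_totals.shape[0] != n or len(self.design) != n:
            raise DomainError("numerator_counts, pair_totals and design must share one length")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise DomainError("sample_ids length mismatch")
        if np.any(self.numerator_counts < 0) or np.any(self.pair_totals < 0):
            raise DomainError("counts must be non-negative")
        if np.any(self.numerator_counts > self.pair_totals):
            raise DomainError("numerator count exceeds pairwise total")

    @property
    def denominator_counts(self) -> np.ndarray:
        return self.pair_totals - self.numerator_counts

    @property
    def n_samples(self) -> int:
        return int(self.numerator_counts.shape[0])

    def swapped(self) -> "PairData":
        """The same pair with numerator and denominator exchanged."""
        return PairData(
            numerator_counts=self.denominator_counts.copy(),
            pair_totals=self.pair_totals.copy(),
            design=self.design.copy(),
            sample_ids=None if self.sample_ids is None else np.asarray(self.sample_ids).copy(),
        )


@dataclass(frozen=True)
class BetaBinomialParams:
    """Beta-binomial parameters in the (mu, phi) parameterization.

    mu is the expected pairwise proportion, phi in [0, 1) the
    extra-binomial correlation. Derived quantities: theta = phi/(1-phi),
    alpha1 = mu/theta, alpha2 = (1-mu)/theta.
    """

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise DomainError(f"mu must lie in (0,1), got {self.mu}")
        if not (0.0 <= self.phi < 1.0):
            raise DomainError(f"phi must lie in [0,1), got {self.phi}")

    @property
    def theta(self) -> float:
        return self.phi / (1.0 - self.phi)

    @property
    def alpha1(self) -> float:
        return self.mu / self.theta

    @property
    def alpha2(self) -> float:
        return (1.0 - self.mu) / self.theta

    @classmethod
    def from_mu_theta(cls, mu: float, theta: float) -> "BetaBinomialParams":
        if theta < 0:
            raise DomainError("theta must be non-negative")
        return cls(mu=mu, phi=theta / (1.0 + theta))

    @classmethod
    def from_alpha(cls, alpha1: float, alpha2: float) -> "BetaBinomialParams":
        if alpha1 <= 0 or alpha2 <= 0:
            raise DomainError("beta shape parameters must be positive")
        return cls.from_mu_theta(alpha1 / (alpha1 + alpha2), 1.0 / (alpha1 + alpha2))


@dataclass
class BetaBinomialFit:
    """Result of one beta-binomial maximum-likelihood fit."""

    beta: np.ndarray
    beta_names: list[str]
    theta_hat: float
    loglik: float
    converged: bool
    n_used: int
    beta_se: np.ndarray | None = None
    status: str = "ok"  # ok | boundary | failed
    message: str = ""
    _nll_args: tuple = field(default=None, repr=False)

    @property
    def phi_hat(self) -> float:
        return self.theta_hat / (1.0 + self.theta_hat)

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def coef_se(self, name: str) -> float:
        if self.beta_se is None:
            self.compute_se()
        return float(self.beta_se[self.beta_names.index(name)])

    def compute_se(self) -> np.ndarray:
        """Standard errors from the inverse observed information.

        The observed information is the Hessian of the negative
        log-likelihood over (beta, log theta), obtained by numerically
        differentiating the analytic gradient at the optimum.
        """
        X, y, t = self._nll_args
        params = np.append(self.beta, np.log(self.theta_hat))
        hess = _numdiff_hessian(params, X, y, t)
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(cov)[: len(self.beta)])
            if not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            se = np.full(len(self.beta), np.nan)
        self.beta_se = se
        return se


@dataclass
class TestResult:
    """A single two-sided test on one taxon pair (or one taxon)."""

    statistic: float
    df: float
    p_value: float
    estimate: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    method_tag: str = ""
    valid: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# probability functions


def _validate_counts(y, t) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    t = np.asarray(t)
    if np.any(y < 0) or np.any(t < 0) or np.any(y > t):
        raise DomainError("require 0 <= y <= t")
    return y, t


def betabin_logpmf(y, t, params: BetaBinomialParams):
    """Log pmf of the beta-binomial via log-Beta functions.

    Stable for totals up to at least 1e6 (no factorials are formed). For
    dispersion below 1e-6 the exact binomial limit is returned.
    """
    y, t = _validate_counts(y, t)
    if params.theta < _THETA_BINOMIAL_LIMIT:
        return stats.binom.logpmf(y, t, params.mu)
    a1, a2 = params.alpha1, params.alpha2
    logcoef = special.gammaln(t + 1) - special.gammaln(y + 1) - special.gammaln(t - y + 1)
    return logcoef + special.betaln(y + a1, t - y + a2) - special.betaln(a1, a2)


def betabin_proportion_variance(params: BetaBinomialParams, t) -> float:
    """Variance of the observed proportion Y/T.

    Var(Y/T) = [1/T + ((T-1)/T) phi] mu (1 - mu); for large T this tends
    to phi mu (1 - mu), the variance of the latent beta distribution.
    """
    t = np.asarray(t)
    if np.any(t < 1):
        raise DomainError("proportion variance requires t >= 1")
    mu, phi = params.mu, params.phi
    return (1.0 / t + (t - 1.0) / t * phi) * mu * (1.0 - mu)


# ---------------------------------------------------------------------------
# likelihood and gradient on (beta, eta = log theta)


def _nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, t: np.ndarray):
    beta = params[:-1]
    theta = np.exp(params[-1])
    mu = special.expit(X @ beta)
    np.clip(mu, _MU_EPS, 1.0 - _MU_EPS, out=mu)
    a1 = mu / theta
    a2 = (1.0 - mu) / theta
    s = a1 + a2  # = 1/theta, scalar-valued but broadcast as array
    ll = special.betaln(y + a1, t - y + a2) - special.betaln(a1, a2)

    dig_s = special.digamma(s)
    dig_ts = special.digamma(t + s)
    d1 = special.digamma(y + a1) - dig_ts - special.digamma(a1) + dig_s
    d2 = special.digamma(t - y + a2) - dig_ts - special.digamma(a2) + dig_s
    # chain rule: da1/dmu = 1/theta, da2/dmu = -1/theta; da/deta = -a
    dll_deta_i = -a1 * d1 - a2 * d2
    w = (d1 - d2) / theta * mu * (1.0 - mu)
    grad = np.empty(params.shape)
    grad[:-1] = -(X.T @ w)
    grad[-1] = -dll_deta_i.sum()
    return -ll.sum(), grad


def _numdiff_hessian(params: np.ndarray, X, y, t, eps: float = 1e-5) -> np.ndarray:
    """Hessian of the negative log-likelihood by central differences of the
    analytic gradient."""
    k = len(params)
    H = np.empty((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(params[j]))
        up = params.copy()
        up[j] += step
        dn = params.copy()
        dn[j] -= step
        H[j] = (_nll_grad(up, X, y, t)[1] - _nll_grad(dn, X, y, t)[1]) / (2 * step)
    return 0.5 * (H + H.T)


def _log_binom_coef(y: np.ndarray, t: np.ndarray) -> float:
    return float(
        np.sum(special.gammaln(t + 1) - special.gammaln(y + 1) - special.gammaln(t - y + 1))
    )


def design_matrix(data: PairData, covariates: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix from named columns of ``data.design``."""
    if covariates is None:
        covariates = list(data.design.columns)
    cols = [np.ones(data.n_samples)]
    names = ["intercept"]
    for c in covariates:
        if c not in data.design.columns:
            raise DesignError(f"covariate {c!r} not in design columns {list(data.design.columns)}")
        cols.append(np.asarray(data.design[c], dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _logistic_init(X: np.ndarray, y: np.ndarray, t: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Quick binomial-logistic IRLS used only to seed the optimizer."""
    p = (y.sum() + 0.5) / (t.sum() + 1.0)
    beta = np.zeros(X.shape[1])
    beta[0] = special.logit(p)
    for _ in range(n_iter):
        mu = special.expit(X @ beta)
        np.clip(mu, 1e-10, 1 - 1e-10, out=mu)
        w = t * mu * (1 - mu)
        z = X @ beta + (y - t * mu) / np.maximum(w, 1e-10)
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X + 1e-8 * np.eye(X.shape[1]), XtW @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        beta_new = np.clip(beta_new, -_BETA_BOUND, _BETA_BOUND)
        if np.max(np.abs(beta_new - beta)) < 1e-6:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _phi_init(X: np.ndarray, y: np.ndarray, t: np.ndarray, beta: np.ndarray) -> float:
    """Method-of-moments dispersion from Pearson residuals, clipped to
    [1e-4, 0.9] on the phi scale."""
    mu = np.clip(special.expit(X @ beta), 1e-10, 1 - 1e-10)
    denom = t * mu * (1 - mu)
    chi2 = float(np.sum((y - t * mu) ** 2 / np.maximum(denom, 1e-10)))
    dof = max(len(y) - X.shape[1], 1)
    tbar = max(float(np.mean(t)) - 1.0, 1.0)
    phi = (chi2 / dof - 1.0) / tbar
    return float(np.clip(phi, 1e-4, 0.9))


def fit_betabin(
    data: PairData,
    covariates: Sequence[str] | None = None,
    compute_se: bool = False,
    max_iter: int = 500,
    ftol: float = 1e-8,
) -> BetaBinomialFit:
    """Maximum-likelihood fit of the beta-binomial pair model.

    Samples with a zero pairwise total carry no information about the pair
    and are dropped before fitting. Optimization is quasi-Newton (L-BFGS-B)
    with the analytic gradient over (beta, log theta); a failed first
    attempt is retried once from (beta = 0, phi = 0.5). Non-convergence is
    recorded on the returned fit, never raised.
    """
    X_all, names = design_matrix(data, covariates)
    mask = data.pair_totals > 0
    n_used = int(mask.sum())
    if n_used == 0:
        raise NoInformationError("all pairwise totals are zero; nothing to fit")
    X = X_all[mask]
    y = data.numerator_counts[mask].astype(float)
    t = data.pair_totals[mask].astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient on informative samples")

    beta0 = _logistic_init(X, y, t)
    phi0 = _phi_init(X, y, t, beta0)
    x0 = np.append(beta0, np.log(phi0 / (1 - phi0)))
    bounds = [(-_BETA_BOUND, _BETA_BOUND)] * X.shape[1] + [_ETA_BOUNDS]

    logcoef = _log_binom_coef(y, t)

    def _run(x_start):
        return optimize.minimize(
            _nll_grad,
            x_start,
            args=(X, y, t),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "maxiter": max_iter},
        )

    res = _run(x0)
    if not (res.success and np.isfinite(res.fun)):
        restart = np.zeros(X.shape[1] + 1)  # beta = 0, phi = 0.5 -> eta = 0
        res2 = _run(restart)
        if res2.success and np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2

    beta_hat = res.x[:-1]
    theta_hat = float(np.exp(res.x[-1]))
    converged = bool(res.success and np.isfinite(res.fun))
    status = "ok"
    if not converged:
        status = "failed"
    elif np.any(np.abs(beta_hat) >= _BETA_BOUND - 1e-6) or not (
        _ETA_BOUNDS[0] + 1e-6 < res.x[-1] < _ETA_BOUNDS[1] - 1e-6
    ):
        status = "boundary"

    fit = BetaBinomialFit(
        beta=beta_hat,
        beta_names=names,
        theta_hat=theta_hat,
        loglik=float(-res.fun + logcoef) if np.isfinite(res.fun) else np.nan,
        converged=converged,
        n_used=n_used,
        status=status,
        message=str(res.message),
        _nll_args=(X, y, t),
    )
    if compute_se:
        fit.compute_se()
    return fit


def lrt_group_effect(
    data: PairData,
    full: Sequence[str] = ("treatment",),
    null: Sequence[str] = (),
    compute_se: bool = False,
    method_tag: str = "bbglm",
) -> TestResult:
    """Likelihood-ratio test of the group effect (H0: beta_1 = 0).

    The null design must be nested in the full design; df is the difference
    in mean-model parameter count and the dispersion is re-estimated under
    each model. The statistic is clamped at zero. A fit that fails outright
    yields an invalid result (no p-value) rather than an exception; boundary
    fits keep their achieved log-likelihoods and still produce a test.
    """
    full = list(full)
    null = list(null)
    if not set(null) <= set(full):
        raise DesignError("null design must be nested in the full design")
    df = len(full) - len(null)
    if df == 0:
        raise DesignError("full and null designs are identical")

    fit_full = fit_betabin(data, covariates=full, compute_se=compute_se)
    fit_null = fit_betabin(data, covariates=null)
    if fit_full.status == "failed" or fit_null.status == "failed":
        return TestResult(
            statistic=np.nan, df=df, p_value=np.nan, method_tag=method_tag,
            valid=False, message="non-converged fit",
        )

    stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(stat, df))
    tested = [c for c in full if c not in null]
    est = fit_full.coef(tested[0]) if len(tested) == 1 else np.nan
    ci_low = ci_high = np.nan
    if compute_se and len(tested) == 1:
        ci_low, ci_high = wald_ci(fit_full, tested[0])
    return TestResult(
        statistic=stat, df=df, p_value=p, estimate=est,
        ci_low=ci_low, ci_high=ci_high, method_tag=method_tag,
        valid=True, message=fit_full.status,
    )


def wald_ci(fit: BetaBinomialFit, coef: str, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for one coefficient.

    For the conventional 95% level the interval is exactly
    estimate +/- 1.96 * se; other levels use the normal quantile.
    """
    est = fit.coef(coef)
    se = fit.coef_se(coef)
    z = 1.96 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2.0))
    return est - z * se, est + z * se
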