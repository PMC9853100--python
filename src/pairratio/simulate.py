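"""Parametric simulation, nonparametric resampling and the power harness.

The parametric generator draws pairwise totals from a totals source, then
for each sample draws the latent proportion p ~ Beta(mu/theta,
(1-mu)/theta) and the count y ~ Binomial(t, p). The control group has
mu = p0 = odds/(1+odds) and the treatment group mu = p0 + delta_p, with the
dispersion theta shared by both groups. A zero total yields a zero count
for both taxa of the pair, which the beta-binomial fit discards and the
log-ratio methods handle through their zero policy.

Two built-in totals surrogates emulate the empirical pairwise-total regimes
of genus-level infant 16S data:

``nonsparse``
    discrete uniform on [9610, 12954] — pairs whose denominator is a
    highly prevalent, abundant genus;
``sparse``
    zero with probability 0.5, otherwise discrete uniform on [1, 9684] —
    pairs whose denominator is a sparse genus.

An explicit array of empirical totals can be supplied instead.

Seeding: every replicate r of a scenario uses an independent generator
``default_rng(SeedSequence(scenario.seed, spawn_key=(r,)))``, so subsets of
replicates and re-runs of single scenarios reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .betabin import PairData, fit_betabin, lrt_group_effect, wald_ci
from .errors import DomainError
from . import logratio
from .pairwise import CountTable

__all__ = [
    "SimulationScenario",
    "scenario_grid",
    "simulate_pair",
    "resample_null",
    "run_power_study",
    "run_coverage_study",
    "make_fixture_table",
    "SIM_METHODS",
]

SIM_METHODS = ("bbglm", "lrlm", "lrlm_2", "lrw", "lrp")

NONSPARSE_TOTALS_RANGE = (9610, 12954)
SPARSE_TOTALS_RANGE = (1, 9684)
SPARSE_ZERO_PROB = 0.5


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the power/type-I study grid.

    ``control_odds`` fixes the control-group proportion p0 = odds/(1+odds);
    ``delta_p`` is the additive treatment shift in expected proportion
    (0 for a null scenario); ``theta`` the shared dispersion; ``n`` the total
    sample size split into two balanced groups; ``totals_source`` one of
    "nonsparse", "sparse" or an array of empirical pairwise totals.
    """

    control_odds: float
    delta_p: float
    theta: float
    n: int
    totals_source: object = None  # "nonsparse" | "sparse" | array-like
    n_reps: int = 10000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        p0 = self.p0
        if not (0.0 < p0 < 1.0) or not (0.0 < p0 + self.delta_p < 1.0):
            raise DomainError("control and treatment proportions must lie in (0,1)")
        if self.delta_p < 0:
            raise DomainError("delta_p must be non-negative")
        if self.theta <= 0:
            raise DomainError("theta must be positive")
        if self.n < 4 or self.n % 2:
            raise DomainError("n must be even and at least 4 (balanced groups)")

    @property
    def p0(self) -> float:
        return self.control_odds / (1.0 + self.control_odds)

    @property
    def p1(self) -> float:
        return self.p0 + self.delta_p

    def resolve_totals_source(self) -> object:
        if self.totals_source is not None:
            return self.totals_source
        # default surrogate regime follows the dispersion archetype:
        # low dispersion <-> abundant denominator, high <-> sparse
        return "nonsparse" if self.theta <= 1.0 else "sparse"


def scenario_grid(
    odds: Sequence[float] = (1.0, 1 / 9, 1 / 99, 1 / 999),
    thetas: Sequence[float] = (0.46, 5.39),
    ns: Sequence[int] = (20, 40, 60, 80, 100, 200),
    delta_p: float = 0.0,
    n_reps: int = 10000,
    seed: int = 0,
) -> list[SimulationScenario]:
    """The full factorial scenario grid (24 cells per dispersion at one delta_p)."""
    grid = []
    i = 0
    for theta in thetas:
        for o in odds:
            for n in ns:
                grid.append(SimulationScenario(
                    control_odds=o, delta_p=delta_p, theta=theta, n=n,
                    n_reps=n_reps, seed=seed + i))
                i += 1
    return grid


def _draw_totals(source, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(source, str):
        if source == "nonsparse":
            lo, hi = NONSPARSE_TOTALS_RANGE
            return rng.integers(lo, hi + 1, size=size)
        if source == "sparse":
            lo, hi = SPARSE_TOTALS_RANGE
            t = rng.integers(lo, hi + 1, size=size)
            t[rng.random(size) < SPARSE_ZERO_PROB] = 0
            return t
        raise DomainError(f"unknown totals source {source!r}")
    arr = np.asarray(source)
    if arr.ndim != 1 or len(arr) == 0 or np.any(arr < 0):
        raise DomainError("empirical totals must be a non-empty 1-d non-negative array")
    return rng.choice(arr, size=size, replace=True)


def draw_betabin_counts(t: np.ndarray, mu: np.ndarray, theta: float,
                        rng: np.random.Generator) -> np.ndarray:
    """y ~ BetaBinomial(t, mu, theta), elementwise; theta -> 0 is binomial."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), t.shape)
    if theta < 1e-8:
        return rng.binomial(t, mu)
    p = rng.beta(mu / theta, (1.0 - mu) / theta)
    return rng.binomial(t, p)


def simulate_pair(
    scenario: SimulationScenario,
    group_labels: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PairData:
    """One replicate of pair data under a scenario.

    ``group_labels`` defaults to a balanced 0/1 split; totals are drawn
    i.i.d. with replacement from the scenario's totals source.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if group_labels is None:
        group_labels = np.repeat([0, 1], scenario.n // 2)
    group_labels = np.asarray(group_labels)
    t = _draw_totals(scenario.resolve_totals_source(), len(group_labels), rng)
    mu = np.where(group_labels == 1, scenario.p1, scenario.p0)
    y = draw_betabin_counts(t, mu, scenario.theta, rng)
    return PairData(
        numerator_counts=y,
        pair_totals=t,
        design=pd.DataFrame({"treatment": group_labels}),
    )


def resample_null(pair_archive: PairData, n: int,
                  rng: np.random.Generator | int | None = 0) -> PairData:
    """Nonparametric null resample of real pair data from two studies.

    Draws n/2 samples with replacement from each study and randomly labels
    half of each study's draw as treatment and half as control, so any
    group difference in the output is pure noise. The study indicator is
    retained for study-adjusted fits.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if "study" not in pair_archive.design.columns:
        raise DomainError("pair archive must carry a 'study' design column")
    if n % 2 or (n // 2) % 2:
        raise DomainError("n/2 samples per study must split into two equal groups; "
                          "n must be a multiple of 4")
    studies = np.unique(np.asarray(pair_archive.design["study"]))
    if len(studies) != 2:
        raise DomainError("exactly two studies are required")
    half = n // 2
    ys, ts, study_col, treat_col = [], [], [], []
    for s in studies:
        pool = np.flatnonzero(np.asarray(pair_archive.design["study"]) == s)
        take = rng.choice(pool, size=half, replace=True)
        ys.append(pair_archive.numerator_counts[take])
        ts.append(pair_archive.pair_totals[take])
        study_col.append(np.full(half, s))
        lab = np.repeat([0, 1], half // 2)
        rng.shuffle(lab)
        treat_col.append(lab)
    return PairData(
        numerator_counts=np.concatenate(ys),
        pair_totals=np.concatenate(ts),
        design=pd.DataFrame({
            "treatment": np.concatenate(treat_col),
            "study": (np.concatenate(study_col) == studies[1]).astype(int),
        }),
    )


def _apply_method(method: str, data: PairData, covariates: list[str],
                  alpha: float, n_perm: int, rng: np.random.Generator,
                  min_per_group: int = 2):
    """p-value of one method on one replicate, or None when inestimable."""
    if method == "bbglm":
        tt = data.pair_totals
        g = np.asarray(data.design["treatment"])
        if min(((tt > 0) & (g == 0)).sum(), ((tt > 0) & (g == 1)).sum()) < min_per_group:
            return None
        res = lrt_group_effect(data, full=covariates,
                               null=[c for c in covariates if c != "treatment"])
        return res.p_value if res.valid else None
    policy = "drop_double" if method == "lrlm_2" else "impute"
    try:
        sample = logratio.log_ratio_transform(data, zero_policy=policy)
        if method in ("lrlm", "lrlm_2"):
            return logratio.lrlm_test(sample, covariates=covariates,
                                      method_tag=method).p_value
        if method == "lrw":
            return logratio.lrw_test(sample).p_value
        if method == "lrp":
            return logratio.lrp_test(sample, n_perm=n_perm, seed=rng).p_value
    except Exception:
        return None
    raise DomainError(f"unknown method {method!r}")


def _rep_rng(scenario: SimulationScenario, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=(rep,)))


def run_power_study(
    scenarios: Iterable[SimulationScenario],
    methods: Sequence[str] = SIM_METHODS,
    n_perm: int = 999,
    rep_start: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Rejection fractions (type-I error when delta_p = 0, power otherwise).

    Each replicate's data are generated once and shared across methods, so
    the result is invariant to method ordering. Replicate seeds are derived
    by counter from the scenario seed; ``rep_start`` lets a study be split
    into independently reproducible batches. Returns a long-format frame
    with one row per scenario x method: rejection count, number of valid
    replicates, rejection fraction and its Monte-Carlo standard error.
    """
    unknown = set(methods) - set(SIM_METHODS)
    if unknown:
        raise DomainError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for scenario in scenarios:
        rej = {m: 0 for m in methods}
        valid = {m: 0 for m in methods}
        for rep in range(rep_start, rep_start + scenario.n_reps):
            rng = _rep_rng(scenario, rep)
            data = simulate_pair(scenario, rng=rng)
            for m in methods:
                p = _apply_method(m, data, ["treatment"], scenario.alpha, n_perm, rng)
                if p is not None and np.isfinite(p):
                    valid[m] += 1
                    if p < scenario.alpha:
                        rej[m] += 1
        for m in methods:
            nv = valid[m]
            frac = rej[m] / nv if nv else np.nan
            rows.append({
                "control_odds": scenario.control_odds, "p0": scenario.p0,
                "delta_p": scenario.delta_p, "theta": scenario.theta,
                "n": scenario.n, "n_reps": scenario.n_reps, "method": m,
                "metric": "type_i_error" if scenario.delta_p == 0 else "power",
                "n_rejections": rej[m], "n_valid": nv, "n_failed": scenario.n_reps - nv,
                "value": frac,
                "mc_se": np.sqrt(frac * (1 - frac) / nv) if nv else np.nan,
            })
    return pd.DataFrame(rows)


def _ci_to_delta_scale(intercept: float, lo: float, hi: float) -> tuple[float, float]:
    """Map a CI on the group coefficient to the proportion-difference scale.

    Endpoints L, U of the effect CI become invlogit(b0 + L) - invlogit(b0)
    and invlogit(b0 + U) - invlogit(b0), anchored at the fitted control
    intercept. The same mapping serves the log-ratio linear model since a
    pairwise log ratio is the logit of the pairwise proportion.
    """
    base = special.expit(intercept)
    return special.expit(intercept + lo) - base, special.expit(intercept + hi) - base


def run_coverage_study(
    scenarios: Iterable[SimulationScenario],
    methods: Sequence[str] = ("bbglm", "lrlm"),
    rep_start: int = 0,
) -> pd.DataFrame:
    """95% CI coverage of the true effect, per scenario and method.

    Coverage is reported on two scales: the proportion-difference scale
    (does the mapped CI contain delta_p) and the model's own effect scale
    (does the CI on the group coefficient contain the true log odds ratio
    logit(p1) - logit(p0)). Replicates whose fit fails are excluded and
    counted.
    """
    rows = []
    for scenario in scenarios:
        true_lor = special.logit(scenario.p1) - special.logit(scenario.p0)
        hits_delta = {m: 0 for m in methods}
        hits_lor = {m: 0 for m in methods}
        valid = {m: 0 for m in methods}
        for rep in range(rep_start, rep_start + scenario.n_reps):
            rng = _rep_rng(scenario, rep)
            data = simulate_pair(scenario, rng=rng)
            for m in methods:
                try:
                    if m == "bbglm":
                        fit = fit_betabin(data, covariates=["treatment"], compute_se=True)
                        if fit.status == "failed" or not np.all(np.isfinite(fit.beta_se)):
                            continue
                        b0 = fit.coef("intercept")
                        lo, hi = wald_ci(fit, "treatment")
                    elif m == "lrlm":
                        sample = logratio.log_ratio_transform(data, zero_policy="impute")
                        res = logratio.lrlm_test(sample)
                        b0 = res.estimate  # placeholder, replaced below
                        # recover the intercept: mean of control-group log ratios
                        g = sample.groups()
                        b0 = float(np.mean(sample.values()[g == 0]))
                        lo, hi = res.ci_low, res.ci_high
                    else:
                        raise DomainError(f"coverage supports bbglm and lrlm, not {m!r}")
                except Exception:
                    continue
                if not (np.isfinite(lo) and np.isfinite(hi)):
                    continue
                valid[m] += 1
                dlo, dhi = _ci_to_delta_scale(b0, lo, hi)
                if dlo <= scenario.delta_p <= dhi:
                    hits_delta[m] += 1
                if lo <= true_lor <= hi:
                    hits_lor[m] += 1
        for m in methods:
            nv = valid[m]
            for scale, hits in (("delta_p", hits_delta[m]), ("log_odds", hits_lor[m])):
                frac = hits / nv if nv else np.nan
                rows.append({
                    "control_odds": scenario.control_odds, "delta_p": scenario.delta_p,
                    "theta": scenario.theta, "n": scenario.n, "n_reps": scenario.n_reps,
                    "method": m, "metric": f"coverage_{scale}", "n_valid": nv,
                    "n_failed": scenario.n_reps - nv, "value": frac,
                    "mc_se": np.sqrt(frac * (1 - frac) / nv) if nv else np.nan,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic fixture tables


def make_fixture_table(
    k_taxa: int = 50,
    n_samples: int = 80,
    sparsity_profile: Sequence[float] | None = None,
    effect_spec: dict | None = None,
    seed: int = 0,
    two_study: bool = True,
    library_size_mean: float = 2e4,
    overdispersion_sd: float = 1.2,
    dominant_share: float = 0.35,
    base_weights: Sequence[float] | None = None,
) -> CountTable:
    """A genus-level-like synthetic count table for tests and demos.

    Emulates the salient features of infant 16S genus tables: one dominant
    taxon, log-scale abundance decay across taxa, heavy per-taxon sparsity
    (``sparsity_profile`` gives per-taxon prevalence; the default mixes
    prevalences from 1.0 down to 0.2, i.e. up to 80% zeros), strong
    sample-to-sample overdispersion, balanced two-group metadata and an
    optional two-study structure. ``effect_spec`` maps taxon ids to a log
    odds effect added to the taxon's latent log-weight in the treatment
    group. Realized prevalence is exact: each taxon is present in exactly
    round(prevalence * n) samples, enforced by raising multinomial sampling
    zeros of present samples to a count of 1. That floor is negligible for
    taxa whose expected counts are well above 1, but it compresses group
    differences for taxa expected at fewer than ~1 read per sample — supply
    ``base_weights`` (relative abundances, overriding the dominant-taxon /
    geometric-decay default) when planted effects on low-weight taxa must be
    distortion-free.
    """
    rng = np.random.default_rng(seed)
    if k_taxa < 2 or n_samples < 4:
        raise DomainError("need at least 2 taxa and 4 samples")
    taxa = [f"taxon_{i+1:02d}" for i in range(k_taxa)]
    samples = [f"s{j+1:03d}" for j in range(n_samples)]

    if sparsity_profile is None:
        # from always-present to 80%-zeros, interleaved
        sparsity_profile = np.linspace(1.0, 0.2, k_taxa)
    prevalence = np.asarray(sparsity_profile, dtype=float)
    if len(prevalence) != k_taxa or np.any(prevalence <= 0) or np.any(prevalence > 1):
        raise DomainError("sparsity_profile must give one prevalence in (0,1] per taxon")

    if base_weights is not None:
        base_weights = np.asarray(base_weights, dtype=float)
        if len(base_weights) != k_taxa or np.any(base_weights <= 0):
            raise DomainError("base_weights must give one positive weight per taxon")
        base_logw = np.log(base_weights / base_weights.sum())
    else:
        # latent log-weights: dominant first taxon, geometric decay for the rest
        base_logw = np.empty(k_taxa)
        base_logw[0] = np.log(dominant_share)
        base_logw[1:] = np.linspace(np.log(0.1), np.log(1e-4), k_taxa - 1)

    group = np.tile([0, 1], n_samples // 2 + 1)[:n_samples]
    study = (np.arange(n_samples) >= n_samples // 2).astype(int) if two_study else np.zeros(n_samples, int)
    study_shift = rng.normal(0.0, 0.25, size=(2, k_taxa)) if two_study else np.zeros((2, k_taxa))

    effect = np.zeros(k_taxa)
    if effect_spec:
        for taxon, eff in effect_spec.items():
            if taxon not in taxa:
                raise DomainError(f"effect_spec names unknown taxon {taxon!r}")
            effect[taxa.index(taxon)] = eff

    # exact presence masks
    present = np.zeros((k_taxa, n_samples), dtype=bool)
    for i, prev in enumerate(prevalence):
        n_present = int(round(prev * n_samples))
        n_present = max(n_present, 1)
        present[i, rng.choice(n_samples, size=n_present, replace=False)] = True

    counts = np.zeros((k_taxa, n_samples), dtype=int)
    libsizes = np.maximum(
        rng.lognormal(np.log(library_size_mean), 0.4, size=n_samples).astype(int), 500
    )
    for j in range(n_samples):
        logw = base_logw + study_shift[study[j]] + rng.normal(0, overdispersion_sd, k_taxa)
        if group[j] == 1:
            logw = logw + effect
        w = np.where(present[:, j], np.exp(logw), 0.0)
        if w.sum() == 0:
            w[0] = 1.0
        counts[:, j] = rng.multinomial(libsizes[j], w / w.sum())
    # guarantee the requested prevalence survives multinomial rounding
    counts[present & (counts == 0)] = 1
    counts[~present] = 0

    metadata = pd.DataFrame(
        {"group": np.where(group == 1, "treatment", "control"),
         "study": np.where(study == 1, "study_B", "study_A")},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountTable(counts=pd.DataFrame(counts, index=taxa, columns=samples),
                      metadata=metadata)
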