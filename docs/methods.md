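# Methods

## The model

`pairratio` performs differential abundance analysis of 16S count tables on
the level of taxon *pairs*. For taxa *a* and *b* in sample *i*, write
Y_ia for the count of *a* and T_iab = Y_ia + Y_ib for the pairwise total.
The model is

    Y_ia | (P_i, T_iab) ~ Binomial(T_iab, P_i),       P_i ~ Beta(α1_i, α2_i),

with mean μ_i = α1_i/(α1_i + α2_i) and dispersion θ = 1/(α1_i + α2_i). The
mean is given a logit-linear predictor, logit(μ_i) = x_i′β; for a two-group
comparison β0 is the control-group log odds of *a* versus *b* and β1 the
treatment difference in log odds, so exp(β1) is the between-group odds ratio
of the pair. The variance of the observed proportion is

    Var(Y/T) = [1/T + ((T−1)/T)·φ]·μ(1−μ),  φ = θ/(1+θ),

which tends to the latent beta variance φμ(1−μ) for large totals: with deep
sequencing, between-sample heterogeneity dominates counting noise.

Working on pairwise totals rather than library totals makes the inference
subcompositionally coherent: a pair's result depends only on the two taxa
involved, so adding or removing other taxa cannot change it, and no library
normalization (with its attendant assumptions) is needed. Zeros need no
imputation — a sample with T = 0 simply carries no information about the
pair and is dropped from that pair's fit.

### Assumptions

- Counts of a pair, conditioned on the pairwise total, are exchangeable
  across samples within a covariate cell (no subject-level random effects).
- One dispersion per pair, shared across groups and not covariate-dependent.
- Group effects act on the logit of the expected pairwise proportion.

## Estimation and testing

Maximum likelihood over (β, log θ). Because η = logit(φ) = log(θ)
identically, the optimizer's dispersion coordinate is simultaneously the
bounded-correlation and log-dispersion parameterization. The log-likelihood
uses log-Beta functions only (stable to totals of at least 10⁶); below
θ = 10⁻⁶ the pmf switches to the exact binomial limit, where differences of
log-gamma values of order 10¹² would otherwise lose ~10⁻² of absolute
precision.

- **Initialization.** β from a short binomial-logistic IRLS; φ from a
  method-of-moments estimate on Pearson residuals, clipped to
  [10⁻⁴, 0.9]; one fallback restart from (β = 0, φ = 0.5).
- **Optimization.** L-BFGS-B with the analytic gradient; box
  |β_j| ≤ 30, θ ∈ [10⁻⁶, 10⁴]; relative tolerance 10⁻⁸, at most 500
  iterations. Non-convergence is recorded on the fit object
  (`status="failed"`), never raised inside batch runs.
- **Boundary fits.** Complete separation (e.g. an all-zero numerator in one
  group) drives β̂ to the box; the fit is flagged `boundary` but its
  achieved log-likelihood is kept, so the LRT below is still computed.
- **Standard errors** come from inverting the observed information over
  (β, log θ), obtained by central differences of the analytic gradient at
  the optimum. They are computed lazily: simulation loops that only need
  p-values skip them.
- **Testing.** H0: β1 = 0 by likelihood ratio against chi-square with df =
  difference in mean-model parameters (1 for a single group effect);
  the dispersion is re-estimated under both the null and full models.
  The 95% Wald interval is exactly β̂1 ± 1.96·se(β̂1).

## Pairwise orchestration

All k(k−1)/2 unordered pairs are fitted once, with the first taxon in table
order as numerator; the reversed orientation is the sign flip of the
estimate, never a refit. Benjamini–Hochberg is applied across all tested
ratios of one treatment comparison (via `statsmodels.multipletests`). Two
bookkeeping rules, both configurable:

- **Minimum-information rule** (default 5): a pair is skipped unless each
  group has at least 5 samples with T > 0. Skipped and non-converged pairs
  contribute no p-value and are excluded from the BH family size m; setting
  the threshold to 0 fits every pair regardless.
- **Prevalence filter** (default 20%): taxa with nonzero counts in fewer
  than ceil(0.2·n) samples are removed before analysis. Sparse taxa mostly
  generate underpowered comparisons that inflate the multiplicity burden.

Results feed a symmetric significance grid (q < 0.05 by default, optionally
restricted to taxa with at least one significant ratio) and two taxon
rankings: *unwrapping* (greedily pick the taxon with the most remaining
significant ratios, remove its ratios, repeat — the selected set accounts
for every significant ratio) and plain *incident counts*. Ties break by
table order in both.

The *MWW mode* is the relative-abundance comparator: each taxon is modelled
against the sample's library total with the same machinery, BH across taxa.
It is subject to closure bias — a genuine absolute shift in one dominant
taxon can flag unshifted taxa — which is precisely the artifact the
pairwise analysis avoids.

## Log-ratio reference methods

The transformation-based comparators share Y′_i = log(Y_ia/Y_ib) after a
zero policy: `impute` (add a pseudocount, default 1, to every zero count),
`drop_double` (remove double-zero samples, impute remaining single zeros),
`drop_any` (remove every zero-containing sample). On zero-free data all
three coincide.

- **lrlm** — OLS on Y′ with a Wald t-test on the group coefficient;
  algebraically the classic two-sample t-test when no covariate is present.
  Implemented as closed-form OLS (it runs ~10⁵ times inside simulation
  loops); agreement with statsmodels OLS and with `scipy.stats.ttest_ind`
  is asserted in the test suite.
- **lrlm_2** — lrlm with the `drop_double` policy. The method description
  and the figure annotations of the source analyses disagree on whether
  *any* zero-containing sample is dropped; this package follows the method
  description (`drop_double`) and exposes `drop_any` via configuration.
- **lrw** — two-sided Wilcoxon rank-sum on Y′; exact enumeration when both
  groups have ≤ 10 tie-free samples, otherwise the normal approximation
  with tie and continuity corrections. Never covariate-adjusted.
- **lrp** — permutation test on the difference of group means of Y′
  (the natural analogue of the lrlm group coefficient; the choice of
  statistic was open). Labels are permuted globally, ignoring study
  structure; two-sided p by the add-one estimator, so p ≥ 1/(n_perm+1) > 0.
  Default 10⁴ permutations per call; the simulation harness uses 999
  (p-value resolution 10⁻³, ample at α = 0.05 given Monte-Carlo error).

## Simulation and resampling harness

**Parametric generator.** Totals are drawn i.i.d. from a totals source;
then p ~ Beta(μ/θ, (1−μ)/θ) and y ~ Binomial(t, p) per sample, with
μ = p0 = odds/(1+odds) in the control group and p0 + Δp under treatment,
dispersion shared. The scenario grid crosses control odds
{1/1, 1/9, 1/99, 1/999} × dispersion {0.46, 5.39} × n ∈ {20..200}
(balanced groups); Δp = 0 gives the type-I scenarios.

**Totals surrogates.** Without an empirical table, `nonsparse` draws
discrete-uniform on [9610, 12954] (the median pairwise-total range for
pairs anchored on a highly abundant genus) and `sparse` is zero with
probability 0.5, else discrete-uniform on [1, 9684] (pairs anchored on a
genus with ~80% zeros). These are deliberate, documented approximations of
the empirical totals distributions, which are not publicly available; a
zero total yields zero counts for both taxa regardless of parameters. An
explicit array of empirical totals can be supplied instead.

**Resampling.** `resample_null` draws n/2 samples with replacement from
each of two studies and randomly splits each study's draw into equal
treatment/control halves, so the group null holds by construction while all
marginal data features are real. bbglm and lrlm then fit study + treatment;
lrw/lrp stay unadjusted.

**Bookkeeping.** Rejection fractions are computed over replicates with a
valid p-value; failures are counted and reported alongside. MC standard
error is sqrt(f(1−f)/n_valid). Every replicate r of a scenario uses
`default_rng(SeedSequence(scenario.seed, spawn_key=(r,)))`: results are
invariant to method ordering (data are generated once per replicate and
shared) and to splitting replicates across batches.

**Coverage.** The 95% CI on the group effect is mapped to the
proportion-difference scale as
[invlogit(β̂0 + L) − invlogit(β̂0), invlogit(β̂0 + U) − invlogit(β̂0)],
anchored at the fitted control intercept; for lrlm the intercept is the
control-group mean log ratio (a pairwise log ratio is the logit of the
pairwise proportion, so the same mapping applies). Because the assessment
scale was an open choice, coverage is reported on both the
proportion-difference and the log-odds scale.

**Fixture generator.** `make_fixture_table` emulates a genus-level table:
one dominant taxon with geometric abundance decay (or explicit
`base_weights`), exact per-taxon prevalence, log-normal library sizes,
strong lognormal sample-to-sample overdispersion, balanced two-group and
optional two-study structure, and planted log-odds effects on chosen taxa.
Realized prevalence is made exact by raising multinomial sampling zeros of
"present" samples to a count of 1; this floor compresses group differences
for taxa expected at under ~1 read per sample, so planted-effect tests use
comparably abundant taxa. The generator reproduces sparsity, dispersion and
compositional closure, but not real taxon–taxon correlation structure or
subject-level covariates — passing tests demonstrate correct behavior under
the model family and realistic marginals, not performance guarantees on any
particular real cohort.

## Problem sizes used in the shipped studies

The package's own acceptance runs use 2000 replicates per null scenario
(48 scenarios, all five methods) and 1000 replicates for the power and
coverage checks, with 999 permutations for lrp. At these sizes the MC
standard error of a rejection fraction near 0.05–0.10 is below 0.007, and
all assertions allow two MC standard errors of slack. Larger replicate
counts (the `n_reps` default is 10⁴) sharpen the estimates but do not
change any qualitative conclusion.

## Known limitations

- No random effects or dispersion covariates; two-level group and study
  factors only.
- The totals surrogates are stylized; empirical totals should be supplied
  when the original pairwise totals are available.
- Boundary fits keep their achieved log-likelihood in the LRT; the
  chi-square reference is approximate there (as it is for any method at
  complete separation).
- The MWW mode is provided for comparison and inherits closure bias by
  design.
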