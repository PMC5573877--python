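# Methods

## Model class and estimation

`mgcfa` fits covariance-structure models of the form
`Σ_g(θ) = Λ_g Ψ_g Λ_gᵀ + Θ_g` to G groups simultaneously. Mean structure
is excluded: all reported χ² values concern covariances only. The free
parameters per group are the on-target loadings (plus any explicitly
freed cross-loadings), all residual variances, explicitly freed residual
covariances, and all factor covariances. Identification fixes every
factor variance at 1, so all loadings are estimable in every group — the
parameterization a configural-invariance analysis needs, since no
constraint ties parameters across groups.

The discrepancy is the normal-theory ML fitting function

    F(θ) = Σ_g (n_g/N) [ ln|Σ_g| − ln|S_g| + tr(S_g Σ_g⁻¹) − p ],

with `S_g` computed with divisor `n_g` and the test statistic `T = N·F_min`
(no N−1 or N−G correction). This pair of conventions is the one that
reproduces published multigroup CFA χ² values from raw data and from
population matrices supplied as moments, and moment-matrix input is a
first-class path: `moments_from_matrices` lets population covariances be
"fit" at a nominal n to study approximation error free of sampling error.

**Optimization.** Fisher scoring: Newton steps on the expected
information (which is cheap, positive semidefinite, and exact at an
exactly fitting optimum) with step halving and a tiny ridge, declared
converged when the ∞-norm of ∂F/∂θ falls below 1e−6 (maximum 500
iterations). If scoring stalls, an L-BFGS-B polish runs on the same
analytic gradient. Non-positive-definite implied covariances during a
line search return a large penalty value, steering the search back into
the PD region. Residual variances are not transformed: Heywood cases
(negative residual variances) remain representable and are flagged on the
result rather than prevented, matching common SEM practice. Starting
values are loadings `0.7·sd(indicator)`, residual variances
`0.5·var(indicator)`, covariances 0; warm starts (e.g., the observed fit's
estimates inside the permutation loop, or previous estimates plus the EPC
for a newly freed parameter) cut iteration counts roughly in half.

For configural models every group has the same parameter layout, so the
objective, gradient and expected information are evaluated for all groups
in one stacked array pass; the general per-group path handles
heterogeneous layouts (e.g., a parameter freed in a single group) and the
two agree to machine precision.

## Fit indices

CFI is computed against the per-group independence baseline (variances
free, all covariances 0), whose ML solution is closed-form:
`T_b = Σ_g n_g (ln|diag S_g| − ln|S_g|)`, `df_b = G·p(p−1)/2`. The
multigroup RMSEA point estimate is `√G · √(max(T−df,0)/(df·N))`; the 90%
CI inverts the noncentral χ²(df, λ) CDF in λ by bracketed root-finding
(tolerance 1e−8, bounds clamped at 0), then maps λ to the RMSEA scale.
The `√G` multiplier with N (not N−G) in the denominator is adopted
because it reproduces published two-group and four-group RMSEA values
exactly from their printed (T, df, N, G); the CI inversion is verified by
plugging the solved λ back into the CDF. Decision thresholds default to
CFI < 0.95 and RMSEA > 0.06 and are configurable.

## Score tests (modification indices)

For a fitted restricted model, the gradient and expected information are
extended over candidate parameters — every cross-loading and residual
covariance fixed to zero in all groups; factor (co)variances are never
candidates. With the log-likelihood score `s = −(N/2)·∂F/∂θ` and
information `I = (N/2)·E[∂²F]`, the modification index for candidate set
A is

    MI = s_Aᵀ (I_AA − I_Aθ I_θθ⁻¹ I_θA)⁻¹ s_A ,

the score (Lagrange multiplier) statistic conditioning on all free
parameters. The univariate MI takes A = one parameter in one group; the
multivariate MI takes A = the same parameter identity in all G groups
(df = G). Because no parameter is shared across groups the information is
block-diagonal over groups, so the multivariate MI equals the sum of its
per-group univariate MIs exactly — asserted in tests at 1e−8 relative
tolerance and implemented through an explicit joint-covariance solve
rather than by summation, so the identity is a check rather than an
assumption. The expected parameter change is the Newton step
`EPC = I_cond⁻¹ s_A` (predicted value of the freed parameter); SEPC
rescales loadings by `√ψ_kk/√σ̂_ii` and residual covariances by
`1/√(σ̂_ii σ̂_jj)` using model-implied variances. Candidates whose
conditioned information is numerically singular (relative tolerance
1e−12) report MI = NaN with a warning and are never treated as zero or
selected.

Expected (not observed) information is used throughout, matching the
convention of mainstream SEM score-test implementations. The score test
agrees with the refit likelihood-ratio statistic asymptotically under
*local* misfit; the test suite pins this at 1% relative agreement on
population moments at n = 5,000 per group with small omitted covariances.
Under gross misspecification the two statistics legitimately diverge
(observed ratios around 0.85–1.05 at the study's effect sizes), which is
a property of the statistics, not an implementation artifact.

## Permutation test of configural invariance

Rows are reassigned to groups uniformly at random (group sizes fixed),
the configural model is refit, and χ², CFI and RMSEA are recorded;
repeating B times yields empirical null distributions under "all groups
share one data-generating process", whatever that process is. p-values
are the plain proportion of permuted statistics at least as *bad* as
observed (χ², RMSEA: ≥ observed; CFI: ≤ observed); an add-one
`(b+1)/(B+1)` variant is available for users who need p > 0 guarantees.
B defaults to 500 and is configurable; nonconverged permutation fits are
excluded from both numerator and denominator, counted, and warned about
above a 5% failure share. Each permutation consumes an RNG stream spawned
from the seed by replicate index, so parallel execution (joblib)
reproduces serial results bit-for-bit.

## The synthetic-data generator and the Monte Carlo study

`study_population()` encodes the study conditions: four groups, two
factors with three indicators each, loadings 0.6/0.7/0.8, residual
variances 1−λ² (0.64/0.51/0.36), unit factor variances, factor
correlations 0.2/0.3/0.4/0.5 across groups, and residual covariances 0.2
(indicators 1↔4) and 0.15 (indicators 2↔5) present in **all** groups.
The analysis model omits the two covariances: overall fit is wrong
everywhere while configural invariance is exactly true. Samples are
multivariate normal, n = 100 per group. The generator emulates the ideal
conditions of the design — exact normality, exact configural invariance,
equal group sizes, listwise-complete data; it does not emulate ordinal
indicators, non-normal tails, unequal groups or missingness, so passing
rates here say nothing about robustness to those features.

Each replication records: the χ²/CFI/RMSEA rejection decisions, the
permutation-test decision (optional; it dominates runtime and can be
disabled without affecting the other rates), and the modification loop —
compute 4-df multivariate MIs, free the largest one significant at
α = 0.05/21 in all groups, refit, iterate until none is significant. The
Bonferroni denominator stays at the initial candidate count (21) across
iterations, since re-freeing shrinks the candidate set only slightly and
published α levels are single fixed values; per-iteration recomputation
is a one-line change. A replication is flagged for familywise Type I
error if any freed identity is not one of the two truly omitted
covariances; power counts replications freeing at least one, and both.

**Univariate comparison.** As a lower bound on the familywise error of
1-df indices, the first fit's univariate MIs are evaluated at
α = 0.05/84: *in each group*, the largest significant 1-df MI is taken —
mirroring how univariate indices would actually be used, to modify each
group's model separately — and the replication is flagged if any group's
selection targets a truly-zero parameter (identity-level matching: a
residual covariance 1↔4 selected in any group counts as correct).
Selecting instead the single largest significant MI across all 84 yields
a much smaller error rate (≈3% vs ≈7–9% in this design) because the two
true covariances usually dominate the pooled ranking; the per-group
definition is the one consistent with published error magnitudes for
this design and with how the statistic is used in practice.

Nonconverged replications are redrawn up to 3 times, then dropped and
counted (none occur under the default design in practice). Replications
use RNG streams spawned from the design seed by index: results are
identical serially or with `n_jobs > 1`.

**Problem sizes.** The default study profile is reps = 1000 with the
permutation sub-test off (~3 minutes on one CPU); the permutation Type I
error is estimated on a scaled profile of 250 replications × B = 100
permutations (~5 minutes), whose binomial standard error (≈1.4 points at
a 5% rate) is the accuracy the comparison bands use.

## Numerical and design notes

* Covariances are stored canonically with row < col; candidate tables
  sort by MI descending with ties broken by canonical parameter order
  (loadings before residual covariances, then row-major), making
  selection deterministic.
* `lrt_compare` floors Δχ² at 0 and checks nesting by free-set inclusion
  per group; identical specs return (0, 0, p = 1).
* Group order is the order of first appearance in the data; fits are
  invariant to group relabeling and to rescaling any indicator (checked
  to 1e−6 on T).
* Sample covariances with a constant or collinear column raise a
  singular-moments error instead of propagating NaNs; missing values are
  rejected, listwise-complete input is the caller's job.
* The estimator supports n_g ≥ p+1 from raw data; moment-matrix input is
  exempt from that check (population matrices are valid at any nominal n).

## Known limitations

* Only covariance structures: no mean/intercept parameters, hence no
  scalar-invariance machinery; no cross-group equality constraints at all
  (metric/strict invariance testing is out of scope by design).
* Normal-theory ML only: no robust/scaled test statistics, no FIML for
  missing data, no ordinal-indicator estimators.
* The permutation test assumes exchangeable rows under the null; it is
  not a test of *which* groups differ when it rejects, and pairwise
  follow-up testing is not implemented.
* Score-test accuracy degrades under gross misspecification, as for any
  modification index; the iterative loop is a diagnostic aid, not a model
  search with generalization guarantees.
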