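# mgcfa

Multigroup confirmatory factor analysis (CFA) tooling for testing
**configural measurement invariance** — the hypothesis that the same
measurement-model *structure* (pattern of fixed and free loadings) holds in
every group — and for respecifying a configural model that fits poorly.

The package addresses a confound in standard practice: configural
invariance is usually judged by the overall fit of the multigroup model,
but a model can fit poorly while every group still shares the same
data-generating structure. `mgcfa` separates the two questions with:

* a **permutation test of configural invariance** — group labels are
  randomly reassigned and the configural model refit, building empirical
  null distributions for χ², CFI and RMSEA under "groups are equivalent"
  without assuming the model is correct;
* **multivariate (G-df) score-test modification indices** — Lagrange
  multiplier tests of freeing the *same* fixed parameter simultaneously in
  all G groups, with expected parameter changes (EPC/SEPC), so that a
  configurally invariant model is modified identically across groups
  instead of group by group;
* a **Monte Carlo harness** measuring the Type I error and power of the
  iterative modification procedure against traditional 1-df indices.

## Model and statistics

For group g with sample covariance `S_g` (divisor n) and model-implied
covariance `Σ_g(θ) = Λ_g Ψ_g Λ_gᵀ + Θ_g`, maximum likelihood minimizes

    F(θ) = Σ_g (n_g/N) [ ln|Σ_g| − ln|S_g| + tr(S_g Σ_g⁻¹) − p ]

and `T = N·F_min` is referred to χ²(df). Factor variances are fixed at 1
(all loadings estimated); no parameter is shared across groups. CFI uses
the per-group independence baseline; the multigroup RMSEA is
`√G·√(max(T−df,0)/(df·N))` with a 90% CI from inverting the noncentral χ²
distribution. A modification index for a candidate set A is the score
statistic `s_Aᵀ V_A⁻¹ s_A` with `V_A` the expected information of A
conditional on all free parameters; with independent groups the G-df index
is exactly the sum of its per-group 1-df indices.

## Worked example

The built-in study population is a two-factor, six-indicator CFA in four
groups (loadings 0.6/0.7/0.8, unit indicator and factor variances, factor
correlations 0.2–0.5 by group) with two residual covariances — 0.2 between
indicators 1 and 4, 0.15 between 2 and 5 — that the analysis model omits,
so the configural model is misspecified in every group while configural
invariance holds exactly.

```python
from mgcfa import (study_population, analysis_spec, moments_from_matrices,
                   fit, fit_indices, multivariate_mis, modification_loop)

pop = study_population()
spec = analysis_spec(pop)                       # omits the two covariances
moments = moments_from_matrices(
    [pop.implied_covariance(g) for g in range(4)], [100] * 4,
    names=spec.indicators)
res = fit(spec, moments)
idx = fit_indices(res)
print(f"chisq({res.df}) = {res.T:.2f}, p = {res.p_value:.3f}")
print(f"CFI = {idx.cfi:.3f}, RMSEA = {idx.rmsea:.3f} "
      f"[{idx.rmsea_ci_low:.3f}, {idx.rmsea_ci_high:.3f}]")
top = multivariate_mis(res).rows[0]
print(f"largest 4-df MI: theta[{top.ref.row},{top.ref.col}] = {top.mi:.2f}")
trace = modification_loop(spec, moments)
print("freed:", [(r.row, r.col) for r in trace.freed])
```

prints

```
chisq(32) = 54.05, p = 0.009
CFI = 0.962, RMSEA = 0.083 [0.042, 0.120]
largest 4-df MI: theta[0,3] = 32.10
freed: [(0, 3), (1, 4)]
```

The χ² test and RMSEA reject this population-level fit (the model *is*
misspecified), yet the modification loop, driven by 4-df indices with a
Bonferroni-adjusted α = 0.05/21, frees exactly the two truly omitted
residual covariances and then stops.

A command-line interface mirrors the library: `mgcfa fit`, `mgcfa mi`,
`mgcfa permute`, `mgcfa simulate`, `mgcfa generate` (see `--help`). The
model syntax is one factor per line, e.g.

```
visual  =~ x1 + x2 + x3
textual =~ x4 + x5 + x6
speed   =~ x7 + x8 + x9
```

with `a ~~ b` freeing a residual covariance and a repeated indicator
freeing a cross-loading.

The classic Holzinger–Swineford two-school data set is not redistributed
here; if you have the standard CSV export (columns `x1`–`x9` plus
`school`), point the test suite at it with `MGCFA_HS_CSV=/path/to/csv` to
run the worked-example checks, or analyze it directly with `mgcfa fit
--data hs.csv --group school`.

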