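"""Approximate fit indices for multigroup covariance-structure fits.

CFI (Bentler) compares the model's excess noncentrality to that of a
per-group independence baseline.  RMSEA (Steiger & Lind) is the root
mean-squared error of approximation; in the multigroup form used here the
point estimate is

    RMSEA = sqrt(G) * sqrt( max(T - df, 0) / (df * N) )

with total sample size N (not N - G) in the denominator, and the 90%
confidence interval is obtained by inverting the noncentral chi-square
distribution in the noncentrality parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .estimation import FitResult, GroupMoments

__all__ = ["FitIndices", "baseline_fit", "cfi", "rmsea", "rmsea_ci", "fit_indices"]


@dataclass
class BaselineResult:
    """Closed-form fit of the per-group independence (diagonal) model."""

    T: float
    df: int

    @property
    def baseline_T(self) -> float:
        return self.T


@dataclass
class FitIndices:
    cfi: float
    rmsea: float
    rmsea_ci_low: float
    rmsea_ci_high: float
    baseline_T: float
    baseline_df: int


def baseline_fit(moments: GroupMoments) -> BaselineResult:
    """Independence baseline: per-group diagonal covariance, variances free.

    The ML solution is Sigma_g = diag(S_g) in closed form, so
    T_b = sum_g n_g * (ln|diag S_g| - ln|S_g|) and df_b = G * p(p-1)/2.
    """
    T = 0.0
    for g in range(moments.n_groups):
        S = moments.covs[g]
        T += moments.ns[g] * (
            float(np.sum(np.log(np.diag(S)))) - moments.logdet(g)
        )
    p = moments.p
    df = moments.n_groups * p * (p - 1) // 2
    return BaselineResult(T=max(T, 0.0), df=df)


def cfi(fit: FitResult, baseline: BaselineResult | None = None) -> float:
    """Comparative fit index: 1 - max(T-df,0) / max(T-df, Tb-dfb, 0)."""
    if baseline is None:
        baseline = baseline_fit(fit.moments)
    num = max(fit.T - fit.df, 0.0)
    den = max(fit.T - fit.df, baseline.T - baseline.df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def rmsea(fit: FitResult) -> float:
    """Multigroup RMSEA point estimate, sqrt(G)-scaled."""
    if fit.df == 0:
        raise ValueError("RMSEA undefined for a saturated model (df = 0)")
    G = fit.n_groups
    N = fit.total_n
    return float(np.sqrt(G) * np.sqrt(max(fit.T - fit.df, 0.0) / (fit.df * N)))


def _ncp_bounds(T: float, df: int, level: float) -> tuple[float, float]:
    """Noncentrality CI by inverting the noncentral chi-square CDF in lambda.

    lambda_low solves P(X_{df,lambda} <= T) = 1 - (1-level)/2 and lambda_high
    solves P(.) = (1-level)/2; both clamped at 0.  Bisection on
    lambda in [0, 10*T].
    """
    tail = (1.0 - level) / 2.0

    def solve(target: float) -> float:
        def f(lam: float) -> float:
            return stats.ncx2.cdf(T, df, lam) - target if lam > 0 else (
                stats.chi2.cdf(T, df) - target
            )

        if f(0.0) <= 0:  # even lambda=0 puts too little mass below T
            return 0.0
        hi = max(10.0 * T, 1.0)
        if f(hi) > 0:  # pragma: no cover - T would have to be astronomical
            return hi
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))

    return solve(1.0 - tail), solve(tail)


def rmsea_ci(fit: FitResult, level: float = 0.90) -> tuple[float, float]:
    """Confidence interval for the multigroup RMSEA."""
    if fit.df == 0:
        raise ValueError("RMSEA undefined for a saturated model (df = 0)")
    lam_low, lam_high = _ncp_bounds(fit.T, fit.df, level)
    G, N, df = fit.n_groups, fit.total_n, fit.df

    def to_rmsea(lam: float) -> float:
        return float(np.sqrt(G) * np.sqrt(max(lam, 0.0) / (df * N)))

    return to_rmsea(lam_low), to_rmsea(lam_high)


def fit_indices(fit: FitResult, level: float = 0.90) -> FitIndices:
    """CFI and RMSEA (with CI) for a fit, using its own moments' baseline."""
    base = baseline_fit(fit.moments)
    lo, hi = rmsea_ci(fit, level)
    return FitIndices(
        cfi=cfi(fit, base),
        rmsea=rmsea(fit),
        rmsea_ci_low=lo,
        rmsea_ci_high=hi,
        baseline_T=base.T,
        baseline_df=base.df,
    )
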