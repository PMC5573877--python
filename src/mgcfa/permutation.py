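"""Permutation test of configural invariance.

Under the null hypothesis that all groups share one data-generating model
(whatever that model is), group labels are exchangeable.  Randomly
reassigning rows to groups and refitting the configural model therefore
yields an empirical sampling distribution for any fit statistic under the
configural-invariance null -- *without* assuming the fitted model is
correct.  The p-value is the proportion of permuted statistics indicating
worse fit than the observed one (chi-square and RMSEA: greater or equal;
CFI: less or equal).  A poorly fitting but group-equivalent model shifts
the permutation distribution itself, so overall misfit alone does not
trigger rejection -- the point of the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .estimation import GroupMoments, fit, sample_moments
from .fit_indices import baseline_fit, cfi, rmsea
from .model import ModelSpec

__all__ = ["PermutationResult", "permute_labels", "permutation_test"]

STATS = ("chisq", "cfi", "rmsea")


@dataclass
class PermutationResult:
    observed: dict  # statistic -> observed value
    null: dict  # statistic -> np.ndarray of permuted values (converged only)
    p_values: dict  # statistic -> float
    B: int
    n_failed: int
    seed: int | None
    pvalue_method: str

    def reject(self, statistic: str = "chisq", alpha: float = 0.05) -> bool:
        return self.p_values[statistic] < alpha


def permute_labels(
    dataset: pd.DataFrame, rng: np.random.Generator, group_column: str = "group"
) -> pd.DataFrame:
    """Return a copy of the dataset with group labels uniformly shuffled.

    Group sizes and the pooled multiset of indicator rows are preserved;
    only the assignment of rows to groups changes.
    """
    labels = dataset[group_column].to_numpy()
    if len(pd.unique(labels)) < 2:
        raise ValueError("permutation requires at least 2 groups")
    out = dataset.copy()
    out[group_column] = labels[rng.permutation(len(labels))]
    return out


def _stats_for(spec: ModelSpec, moments: GroupMoments, start=None):
    res = fit(spec, moments, start=start)
    if not res.converged:
        return None, res
    base = baseline_fit(moments)
    return (
        {"chisq": res.T, "cfi": cfi(res, base), "rmsea": rmsea(res)},
        res,
    )


def _one_permutation(spec, dataset, group_column, seed_seq, start):
    rng = np.random.default_rng(seed_seq)
    permuted = permute_labels(dataset, rng, group_column)
    try:
        moments = sample_moments(permuted, group_column)
        stats_p, _ = _stats_for(spec, moments, start=start)
    except (ValueError, np.linalg.LinAlgError):
        return None
    return stats_p


def permutation_test(
    spec: ModelSpec,
    dataset: pd.DataFrame,
    B: int = 500,
    seed: int | None = None,
    group_column: str = "group",
    pvalue_method: str = "plain",
    n_jobs: int = 1,
) -> PermutationResult:
    """Permutation test of configural invariance on raw per-subject data.

    Parameters
    ----------
    B
        Number of label permutations.
    pvalue_method
        ``"plain"``: p = (#worse) / B over converged permutations (the
        convention matching "proportion of the distribution that exceeds");
        ``"addone"``: p = (#worse + 1) / (B + 1), never exactly zero.
    n_jobs
        Permutation fits are independent; each uses an RNG stream spawned
        from ``seed`` by replicate index, so parallel results equal serial.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if pvalue_method not in ("plain", "addone"):
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    moments = sample_moments(dataset, group_column)
    observed, obs_fit = _stats_for(spec, moments)
    if observed is None:
        raise RuntimeError("configural model did not converge on observed data")

    if isinstance(seed, np.random.SeedSequence):
        seqs = seed.spawn(B)
    else:
        seqs = np.random.SeedSequence(seed).spawn(B)
    runner = (
        Parallel(n_jobs=n_jobs)(
            delayed(_one_permutation)(spec, dataset, group_column, s, obs_fit.x)
            for s in seqs
        )
        if n_jobs != 1
        else [
            _one_permutation(spec, dataset, group_column, s, obs_fit.x)
            for s in seqs
        ]
    )
    null = {stat: [] for stat in STATS}
    n_failed = 0
    for result in runner:
        if result is None:
            n_failed += 1
            continue
        for stat in STATS:
            null[stat].append(result[stat])
    n_ok = B - n_failed
    if n_ok == 0:
        raise RuntimeError("all permutation fits failed to converge")
    if n_failed > 0.05 * B:
        warnings.warn(
            f"{n_failed}/{B} permutation fits failed to converge; p-values use "
            f"the remaining {n_ok}"
        )
    null = {stat: np.asarray(v) for stat, v in null.items()}
    p_values = {}
    for stat in STATS:
        if stat == "cfi":  # lower CFI = worse fit
            worse = int(np.sum(null[stat] <= observed[stat]))
        else:
            worse = int(np.sum(null[stat] >= observed[stat]))
        if pvalue_method == "plain":
            p_values[stat] = worse / n_ok
        else:
            p_values[stat] = (worse + 1) / (n_ok + 1)
    return PermutationResult(
        observed=observed,
        null=null,
        p_values=p_values,
        B=B,
        n_failed=n_failed,
        seed=seed,
        pvalue_method=pvalue_method,
    )
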