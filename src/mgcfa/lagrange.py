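"""Score-test (Lagrange multiplier) modification indices for multigroup CFA.

A modification index estimates the chi-square improvement from freeing a
fixed-to-zero parameter, computed from the gradient and expected (Fisher)
information of the fitted restricted model -- no refit required.  With the
score vector s and information I of the log-likelihood, partitioned into
free parameters (theta) and a candidate set (A),

    MI = s_A' (I_AA - I_A,theta I_theta,theta^-1 I_theta,A)^-1 s_A ,

which is asymptotically the likelihood-ratio statistic for freeing A.  The
univariate MI takes A = one parameter in one group (1 df).  The
*multivariate* MI takes A = the same parameter identity in every group
(G df), testing the constraint simultaneously across groups.  Because no
parameter is shared across groups, the information is block-diagonal over
groups and the multivariate MI equals the sum of its per-group univariate
MIs.

The expected parameter change (EPC) is the Newton step for the candidate,
EPC = I_cond^-1 s_A, i.e. the value the parameter is predicted to take if
freed; the SEPC rescales it to the completely standardized metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult, _Template, _safe_inv_logdet
from .model import ALL_GROUPS, ParameterRef, _canonical_key
from .model import candidate_constraints as _default_candidates

__all__ = [
    "SingularInformationWarning",
    "ScoreRow",
    "ScoreTable",
    "extended_score_info",
    "univariate_mis",
    "multivariate_mis",
    "sepc",
    "largest_significant",
]


@dataclass
class ScoreRow:
    """One modification-index row: a candidate constraint and its tests."""

    ref: ParameterRef  # group-specific (univariate) or ALL_GROUPS identity
    mi: float
    df: int
    p_value: float
    epc: dict  # group -> raw expected parameter change
    sepc: dict  # group -> completely standardized EPC

    @property
    def groups(self) -> list[int]:
        return sorted(self.epc)


@dataclass
class ScoreTable:
    """Modification indices sorted descending by MI (canonical tie-break)."""

    rows: list[ScoreRow]

    def __post_init__(self) -> None:
        self.rows.sort(
            key=lambda r: (
                -(r.mi if np.isfinite(r.mi) else -np.inf),
                _canonical_key(r.ref),
                r.ref.group,
            )
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "role": r.ref.role,
                    "row": r.ref.row,
                    "col": r.ref.col,
                    "group": "all" if r.ref.group == ALL_GROUPS else r.ref.group,
                    "mi": r.mi,
                    "df": r.df,
                    "p_value": r.p_value,
                    "epc": r.epc[r.groups[0]] if len(r.epc) == 1 else np.nan,
                    "sepc": r.sepc[r.groups[0]] if len(r.sepc) == 1 else np.nan,
                }
            )
        return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# Gradient / information over free + candidate parameters


def _group_derivative(tmpl: _Template, x: np.ndarray, g: int, ref: ParameterRef):
    """dSigma_g/dtheta for a fixed-at-zero candidate parameter."""
    p = tmpl.spec.p
    d = np.zeros((p, p))
    if ref.role == "loading":
        lam, psi, _ = tmpl.matrices(x, g)
        A = lam @ psi
        d[ref.row, :] += A[:, ref.col]
        d[:, ref.row] += A[:, ref.col]
    elif ref.role == "residual_covariance":
        d[ref.row, ref.col] = 1.0
        d[ref.col, ref.row] = 1.0
    else:
        raise ValueError(f"{ref.role} is not a candidate constraint")
    return d


def extended_score_info(
    fit: FitResult, candidates: list[ParameterRef] | None = None
):
    """Gradient and expected information over free + candidate parameters.

    Both are on the scale of the pooled discrepancy F (gradient dF/dtheta,
    expected Hessian of F); the log-likelihood score is -(N/2) * gradient
    and the information is (N/2) * hessian.  Returns, per group ``g``, a
    dict with keys ``grad_free``, ``grad_cand``, ``H_ff``, ``H_cf``,
    ``H_cc`` and the candidate instances ``cand_refs`` (candidates expanded
    into that group).  Cross-group information blocks are structurally zero
    and therefore not represented.
    """
    spec = fit.spec
    if candidates is None:
        candidates = _default_candidates(spec)
    tmpl = _Template(spec)
    from .estimation import _sigma_and_derivs  # local import to avoid cycle

    N = fit.total_n
    out = []
    for g in range(spec.n_groups):
        sigma, d_free = _sigma_and_derivs(tmpl, fit.x, g)
        inv, _ = _safe_inv_logdet(sigma)
        if inv is None:
            raise np.linalg.LinAlgError(f"group {g}: implied covariance not PD")
        S = fit.moments.covs[g]
        w = fit.moments.ns[g] / N
        W = inv - inv @ S @ inv
        cand_refs = [c.in_group(g) for c in candidates]
        d_cand = np.array(
            [_group_derivative(tmpl, fit.x, g, c) for c in candidates]
        ).reshape(len(candidates), spec.p, spec.p)
        d_all = np.concatenate([d_free, d_cand], axis=0)
        grad_all = w * np.tensordot(d_all, W, axes=([1, 2], [0, 1]))
        B = np.einsum("ij,tjk,kl->til", inv, d_all, inv)
        H_all = w * np.tensordot(B, d_all, axes=([1, 2], [1, 2]))
        H_all = (H_all + H_all.T) / 2.0
        nf = d_free.shape[0]
        out.append(
            {
                "group": g,
                "weight": w,
                "cand_refs": cand_refs,
                "grad_free": grad_all[:nf],
                "grad_cand": grad_all[nf:],
                "H_ff": H_all[:nf, :nf],
                "H_cf": H_all[nf:, :nf],
                "H_cc": H_all[nf:, nf:],
            }
        )
    return out


def _conditional_blocks(info_g):
    """Per-candidate conditional variance and score for one group's block.

    Returns (scores, cond_var) where scores are F-scale candidate gradients
    and cond_var[c] = H_cc[c,c] - H_cf[c] H_ff^-1 H_fc[c] (F scale).
    """
    H_ff = info_g["H_ff"]
    H_cf = info_g["H_cf"]
    H_cc = info_g["H_cc"]
    sol = np.linalg.solve(H_ff, H_cf.T)  # (nf, nc)
    cond = np.diag(H_cc) - np.einsum("cf,fc->c", H_cf, sol)
    return info_g["grad_cand"], cond


def _implied_sds(fit: FitResult, g: int):
    return np.sqrt(np.clip(np.diag(fit.implied[g]), 0.0, None))


def sepc(epc: float, fit: FitResult, ref: ParameterRef) -> float:
    """Completely standardized expected parameter change.

    Loadings are rescaled by factor SD over implied indicator SD; residual
    covariances by the product of implied indicator SDs.
    """
    g = ref.group
    if g == ALL_GROUPS:
        raise ValueError("SEPC needs a group-specific parameter")
    sds = _implied_sds(fit, g)
    tmpl = _Template(fit.spec)
    _, psi, _ = tmpl.matrices(fit.x, g)
    if ref.role == "loading":
        s_i = sds[ref.row]
        if s_i <= 0:
            warnings.warn(f"nonpositive implied variance for indicator {ref.row}")
            return float("nan")
        return float(epc * np.sqrt(psi[ref.col, ref.col]) / s_i)
    if ref.role == "residual_covariance":
        s_i, s_j = sds[ref.row], sds[ref.col]
        if s_i <= 0 or s_j <= 0:
            warnings.warn("nonpositive implied variance in residual covariance")
            return float("nan")
        return float(epc / (s_i * s_j))
    raise ValueError(f"no SEPC defined for role {ref.role}")


class SingularInformationWarning(UserWarning):
    """A candidate's conditioned information is numerically singular."""


_SINGULAR_TOL = 1e-12


def univariate_mis(
    fit: FitResult, candidates: list[ParameterRef] | None = None
) -> ScoreTable:
    """1-df modification indices: one row per (candidate, group).

    Each MI estimates the chi-square drop from freeing that parameter in
    that single group, conditioning on the group's free parameters.
    """
    info = extended_score_info(fit, candidates)
    N = fit.total_n
    rows = []
    for block in info:
        grads, cond = _conditional_blocks(block)
        for c, ref in enumerate(block["cand_refs"]):
            v = cond[c]
            if v <= _SINGULAR_TOL * max(block["H_cc"][c, c], 1.0):
                warnings.warn(
                    f"singular conditioned information for {ref}; MI undefined",
                    SingularInformationWarning,
                )
                mi, epc_val = float("nan"), float("nan")
            else:
                mi = float((N / 2.0) * grads[c] ** 2 / v)
                epc_val = float(-grads[c] / v)
            rows.append(
                ScoreRow(
                    ref=ref,
                    mi=mi,
                    df=1,
                    p_value=float(stats.chi2.sf(mi, 1)) if np.isfinite(mi) else 1.0,
                    epc={ref.group: epc_val},
                    sepc={ref.group: sepc(epc_val, fit, ref)
                          if np.isfinite(epc_val) else float("nan")},
                )
            )
    return ScoreTable(rows)


def multivariate_mis(
    fit: FitResult, candidates: list[ParameterRef] | None = None
) -> ScoreTable:
    """G-df modification indices: the same parameter freed in all groups.

    MI = s' V^-1 s over the cross-group candidate set, with V the
    information of the set conditioned on all free parameters.  V is
    block-diagonal over groups (no parameter is shared), so each MI equals
    the sum of the per-group univariate MIs.
    """
    spec = fit.spec
    if candidates is None:
        candidates = _default_candidates(spec)
    info = extended_score_info(fit, candidates)
    N = fit.total_n
    G = spec.n_groups
    # joint conditional covariance of each candidate set is diagonal with the
    # per-group conditional variances; assemble and solve it explicitly.
    per_group = [_conditional_blocks(block) for block in info]
    rows = []
    for c, ident in enumerate(candidates):
        s = np.array([per_group[g][0][c] for g in range(G)])
        V = np.diag([per_group[g][1][c] for g in range(G)])
        if np.any(np.diag(V) <= _SINGULAR_TOL):
            warnings.warn(
                f"singular conditioned information for {ident}; MI undefined",
                SingularInformationWarning,
            )
            mi = float("nan")
            epcs = {g: float("nan") for g in range(G)}
        else:
            step = np.linalg.solve(V, s)
            mi = float((N / 2.0) * s @ step)
            epcs = {g: float(-step[g]) for g in range(G)}
        rows.append(
            ScoreRow(
                ref=ident,
                mi=mi,
                df=G,
                p_value=float(stats.chi2.sf(mi, G)) if np.isfinite(mi) else 1.0,
                epc=epcs,
                sepc={
                    g: sepc(e, fit, ident.in_group(g)) if np.isfinite(e)
                    else float("nan")
                    for g, e in epcs.items()
                },
            )
        )
    return ScoreTable(rows)


def largest_significant(
    table: ScoreTable, alpha_family: float = 0.05, n_tests: int | None = None
) -> ScoreRow | None:
    """Highest-MI row significant at the Bonferroni-adjusted level, or None.

    The per-test level is alpha_family / n_tests (n_tests defaults to the
    table length).  Ties in MI are broken by canonical parameter order,
    which the table's sort already guarantees.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    if n_tests is None:
        n_tests = len(table)
    alpha = alpha_family / n_tests
    for row in table:
        if np.isfinite(row.mi) and row.p_value < alpha:
            return row
    return None
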