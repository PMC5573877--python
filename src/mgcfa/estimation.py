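"""Normal-theory maximum-likelihood estimation of multigroup covariance models.

The discrepancy minimized is the multigroup ML fitting function

    F(theta) = sum_g (n_g / N) [ ln|Sigma_g| - ln|S_g| + tr(S_g Sigma_g^-1) - p ]

with sample covariances computed with divisor n (the ML convention).  The
overall test statistic is T = N * F_min, referred to a central chi-square
with df = G * p(p+1)/2 minus the number of free parameters.  Mean structure
is excluded throughout; groups share no parameters, so the expected
information is block-diagonal across groups.

Optimization is Fisher scoring (Newton steps on the expected information)
with step halving, which converges in a handful of iterations for
well-behaved CFA problems; a quasi-Newton (L-BFGS-B) polish is applied if
scoring stalls.  Residual variances are not transformed, so Heywood cases
(negative estimates) are representable and flagged rather than prevented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, ParameterRef

__all__ = [
    "GroupMoments",
    "FitResult",
    "sample_moments",
    "moments_from_matrices",
    "fml_discrepancy",
    "fit",
    "lrt_compare",
]

#: discrepancy returned when an implied covariance is not positive definite,
#: so that line searches back away from the non-PD region.
_PENALTY = 1e12


class SingularMomentsError(ValueError):
    """A sample covariance matrix is singular (e.g., a constant column)."""


@dataclass
class GroupMoments:
    """Per-group sample (or population) covariance matrices and sizes."""

    names: list[str]
    covs: list[np.ndarray]  # each (p, p), divisor-n convention
    ns: list[int]
    labels: list  # group labels, order of first appearance

    @property
    def n_groups(self) -> int:
        return len(self.covs)

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def total_n(self) -> int:
        return int(sum(self.ns))

    def __post_init__(self) -> None:
        for g, S in enumerate(self.covs):
            S = np.asarray(S, dtype=float)
            if S.shape != (self.p, self.p):
                raise ValueError(
                    f"group {g}: covariance shape {S.shape} != ({self.p}, {self.p})"
                )
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"group {g}: covariance matrix not symmetric")
            self.covs[g] = (S + S.T) / 2.0
        # cache log-determinants; fail loudly on singular moments
        self._logdets = []
        for g, S in enumerate(self.covs):
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0 or not np.isfinite(logdet):
                raise SingularMomentsError(
                    f"group {self.labels[g]!r}: sample covariance is singular "
                    "(constant or collinear columns?)"
                )
            self._logdets.append(logdet)

    def logdet(self, g: int) -> float:
        return self._logdets[g]


def sample_moments(table: pd.DataFrame, group_column: str) -> GroupMoments:
    """Compute per-group divisor-n covariance matrices from raw data.

    Groups are ordered by first appearance in the table.  Missing values are
    rejected: callers must supply listwise-complete data.
    """
    if group_column not in table.columns:
        raise KeyError(f"group column {group_column!r} not in table")
    names = [c for c in table.columns if c != group_column]
    values = table[names]
    if values.isna().any().any():
        raise ValueError(
            "missing values in indicator columns; drop incomplete rows before "
            "computing moments"
        )
    labels = list(pd.unique(table[group_column]))
    covs, ns = [], []
    for lab in labels:
        X = values.loc[table[group_column] == lab].to_numpy(dtype=float)
        n = X.shape[0]
        if n < len(names) + 1:
            raise ValueError(
                f"group {lab!r} has n={n} < p+1={len(names) + 1} observations"
            )
        Xc = X - X.mean(axis=0)
        covs.append(Xc.T @ Xc / n)
        ns.append(n)
    return GroupMoments(names=names, covs=covs, ns=ns, labels=labels)


def moments_from_matrices(
    covs, ns, names: list[str] | None = None, labels=None
) -> GroupMoments:
    """Wrap covariance matrices supplied directly (e.g., population values)."""
    covs = [np.asarray(S, dtype=float) for S in covs]
    p = covs[0].shape[0]
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    if labels is None:
        labels = list(range(1, len(covs) + 1))
    return GroupMoments(names=names, covs=covs, ns=[int(n) for n in ns], labels=labels)


# ---------------------------------------------------------------------------
# Parameter vector <-> matrices


class _Template:
    """Compiled free-parameter layout of a spec: vector <-> (Lambda, Psi, Theta).

    The parameter vector is group-major; within a group the canonical order of
    :meth:`ModelSpec.free_refs` applies.  Per-group index arrays are
    precompiled so that matrix assembly and derivative stacking are pure
    fancy-indexing operations.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.refs: list[ParameterRef] = []
        self.group_slices: list[slice] = []
        self._idx = []  # per group: dict of index arrays
        for g in range(spec.n_groups):
            start = len(self.refs)
            grefs = spec.free_refs(g)
            self.refs.extend(grefs)
            self.group_slices.append(slice(start, len(self.refs)))
            ix = {}
            for role, key in (
                ("loading", "load"),
                ("residual_variance", "rv"),
                ("residual_covariance", "rc"),
                ("factor_covariance", "fc"),
            ):
                sel = [(t, r) for t, r in enumerate(grefs) if r.role == role]
                ix[key + "_t"] = np.array([t for t, _ in sel], dtype=int)
                ix[key + "_i"] = np.array([r.row for _, r in sel], dtype=int)
                ix[key + "_j"] = np.array([r.col for _, r in sel], dtype=int)
            self._idx.append(ix)
        self.n_params = len(self.refs)
        self.index = {ref: i for i, ref in enumerate(self.refs)}
        # configural structure: identical per-group layout enables computing
        # all groups in one stacked pass
        layouts = [
            tuple((r.role, r.row, r.col) for r in spec.free_refs(g))
            for g in range(spec.n_groups)
        ]
        self.homogeneous = all(lay == layouts[0] for lay in layouts)

    def matrices(self, x: np.ndarray, g: int):
        spec = self.spec
        p, m = spec.p, spec.m
        xg = np.asarray(x, dtype=float)[self.group_slices[g]]
        ix = self._idx[g]
        lam = np.zeros((p, m))
        lam[ix["load_i"], ix["load_j"]] = xg[ix["load_t"]]
        psi = np.eye(m)
        psi[ix["fc_i"], ix["fc_j"]] = xg[ix["fc_t"]]
        psi[ix["fc_j"], ix["fc_i"]] = xg[ix["fc_t"]]
        theta = np.zeros((p, p))
        theta[ix["rv_i"], ix["rv_i"]] = xg[ix["rv_t"]]
        theta[ix["rc_i"], ix["rc_j"]] = xg[ix["rc_t"]]
        theta[ix["rc_j"], ix["rc_i"]] = xg[ix["rc_t"]]
        return lam, psi, theta

    def start_values(self, moments: GroupMoments) -> np.ndarray:
        """Robust defaults: loadings 0.7*sd, residual variances 0.5*var,
        covariances 0."""
        x = np.zeros(self.n_params)
        for g in range(self.spec.n_groups):
            s = np.diag(moments.covs[g])
            for i, ref in zip(
                range(*self.group_slices[g].indices(self.n_params)),
                self.refs[self.group_slices[g]],
            ):
                if ref.role == "loading":
                    x[i] = 0.7 * np.sqrt(s[ref.row])
                elif ref.role == "residual_variance":
                    x[i] = 0.5 * s[ref.row]
        return x


def _sigma_and_derivs(tmpl: _Template, x: np.ndarray, g: int):
    """Implied Sigma_g and the stack dSigma/dtheta (k, p, p) for group g."""
    lam, psi, theta = tmpl.matrices(x, g)
    sigma = lam @ psi @ lam.T + theta
    sigma = (sigma + sigma.T) / 2.0
    ix = tmpl._idx[g]
    sl = tmpl.group_slices[g]
    nref = sl.stop - sl.start
    p = tmpl.spec.p
    A = lam @ psi  # (p, m)
    d = np.zeros((nref, p, p))
    # loadings: dSigma/dlam_ik = e_i A_k' + A_k e_i'
    lt, li, lk = ix["load_t"], ix["load_i"], ix["load_j"]
    if lt.size:
        d[lt, li, :] += A[:, lk].T
        d[lt, :, li] += A[:, lk].T
    d[ix["rv_t"], ix["rv_i"], ix["rv_i"]] = 1.0
    d[ix["rc_t"], ix["rc_i"], ix["rc_j"]] = 1.0
    d[ix["rc_t"], ix["rc_j"], ix["rc_i"]] = 1.0
    # factor covariances: lam_k lam_l' + lam_l lam_k'
    for t, k, l in zip(ix["fc_t"], ix["fc_i"], ix["fc_j"]):
        outer = np.outer(lam[:, k], lam[:, l])
        d[t] = outer + outer.T
    return sigma, d


def _safe_inv_logdet(sigma: np.ndarray):
    """Cholesky-based inverse and log-determinant; None if not PD."""
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return None, None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    inv = np.linalg.inv(sigma)
    return inv, logdet


def fml_discrepancy(
    x: np.ndarray, spec_or_tmpl, moments: GroupMoments
) -> float:
    """Multigroup ML discrepancy F at parameter vector ``x`` (>= 0 at S=Sigma)."""
    tmpl = spec_or_tmpl if isinstance(spec_or_tmpl, _Template) else _Template(
        spec_or_tmpl
    )
    N = moments.total_n
    p = moments.p
    F = 0.0
    for g in range(moments.n_groups):
        lam, psi, theta = tmpl.matrices(np.asarray(x, dtype=float), g)
        sigma = lam @ psi @ lam.T + theta
        inv, logdet = _safe_inv_logdet(sigma)
        if inv is None:
            return _PENALTY
        S = moments.covs[g]
        F += (moments.ns[g] / N) * (
            logdet - moments.logdet(g) + float(np.sum(S * inv)) - p
        )
    return F


def _value_and_grad(tmpl: _Template, x: np.ndarray, moments: GroupMoments):
    """(F, dF/dx); returns (_PENALTY, zeros) when any Sigma_g is not PD."""
    N = moments.total_n
    p = moments.p
    F = 0.0
    grad = np.zeros(tmpl.n_params)
    for g in range(moments.n_groups):
        sigma, d = _sigma_and_derivs(tmpl, x, g)
        inv, logdet = _safe_inv_logdet(sigma)
        if inv is None:
            return _PENALTY, grad
        S = moments.covs[g]
        w = moments.ns[g] / N
        F += w * (logdet - moments.logdet(g) + float(np.sum(S * inv)) - p)
        W = inv - inv @ S @ inv  # symmetric
        grad[tmpl.group_slices[g]] = w * np.tensordot(d, W, axes=([1, 2], [0, 1]))
    return F, grad


def _expected_info_F(tmpl: _Template, x: np.ndarray, moments: GroupMoments):
    """Expected Hessian of F: block-diagonal, block_g = w_g * tr(inv d inv d)."""
    N = moments.total_n
    H = np.zeros((tmpl.n_params, tmpl.n_params))
    for g in range(moments.n_groups):
        sigma, d = _sigma_and_derivs(tmpl, x, g)
        inv, _ = _safe_inv_logdet(sigma)
        if inv is None:
            raise np.linalg.LinAlgError("implied covariance not PD")
        B = np.einsum("ij,tjk,kl->til", inv, d, inv)
        block = np.tensordot(B, d, axes=([1, 2], [1, 2]))
        sl = tmpl.group_slices[g]
        H[sl, sl] = (moments.ns[g] / N) * (block + block.T) / 2.0
    return H


def _stacked_sigma_derivs(tmpl: _Template, x: np.ndarray):
    """All groups' Sigma (G,p,p) and dSigma stacks (G,nref,p,p).

    Requires a homogeneous template (identical per-group layout).
    """
    G = tmpl.spec.n_groups
    p = tmpl.spec.p
    ix = tmpl._idx[0]
    nref = tmpl.group_slices[0].stop
    xg = np.asarray(x, dtype=float).reshape(G, nref)
    lam = np.zeros((G, p, tmpl.spec.m))
    lam[:, ix["load_i"], ix["load_j"]] = xg[:, ix["load_t"]]
    psi = np.broadcast_to(np.eye(tmpl.spec.m), (G,) + (tmpl.spec.m,) * 2).copy()
    psi[:, ix["fc_i"], ix["fc_j"]] = xg[:, ix["fc_t"]]
    psi[:, ix["fc_j"], ix["fc_i"]] = xg[:, ix["fc_t"]]
    theta = np.zeros((G, p, p))
    theta[:, ix["rv_i"], ix["rv_i"]] = xg[:, ix["rv_t"]]
    theta[:, ix["rc_i"], ix["rc_j"]] = xg[:, ix["rc_t"]]
    theta[:, ix["rc_j"], ix["rc_i"]] = xg[:, ix["rc_t"]]
    A = lam @ psi  # (G, p, m)
    sigma = A @ lam.transpose(0, 2, 1) + theta
    sigma = (sigma + sigma.transpose(0, 2, 1)) / 2.0
    d = np.zeros((G, nref, p, p))
    lt, li, lk = ix["load_t"], ix["load_i"], ix["load_j"]
    if lt.size:
        contrib = A[:, :, lk]  # (G, p, n_load)
        d[:, lt, li, :] += contrib.transpose(0, 2, 1)
        # fancy indices split by a slice put the index axis first: (n_load, G, p)
        d[:, lt, :, li] += contrib.transpose(2, 0, 1)
    d[:, ix["rv_t"], ix["rv_i"], ix["rv_i"]] = 1.0
    d[:, ix["rc_t"], ix["rc_i"], ix["rc_j"]] = 1.0
    d[:, ix["rc_t"], ix["rc_j"], ix["rc_i"]] = 1.0
    for t, k, l in zip(ix["fc_t"], ix["fc_i"], ix["fc_j"]):
        outer = np.einsum("gp,gq->gpq", lam[:, :, k], lam[:, :, l])
        d[:, t] = outer + outer.transpose(0, 2, 1)
    return sigma, d


def _value_grad_info_batched(tmpl: _Template, x: np.ndarray, moments: GroupMoments):
    """Stacked-group (F, grad, expected Hessian); homogeneous templates only."""
    N = moments.total_n
    p = moments.p
    G = moments.n_groups
    sigma, d = _stacked_sigma_derivs(tmpl, x)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY, np.zeros(tmpl.n_params), np.zeros((tmpl.n_params,) * 2)
    logdets = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    inv = np.linalg.inv(sigma)
    S = np.stack(moments.covs)
    w = np.array(moments.ns, dtype=float) / N
    F = float(
        np.sum(
            w
            * (
                logdets
                - np.array([moments.logdet(g) for g in range(G)])
                + np.einsum("gij,gij->g", S, inv)
                - p
            )
        )
    )
    W = inv - inv @ S @ inv
    grad = (w[:, None] * np.einsum("gtij,gij->gt", d, W)).ravel()
    B = np.einsum("gij,gtjk,gkl->gtil", inv, d, inv)
    block = np.einsum("gtij,guij->gtu", B, d)
    block = w[:, None, None] * (block + block.transpose(0, 2, 1)) / 2.0
    nref = block.shape[1]
    H = np.zeros((tmpl.n_params, tmpl.n_params))
    for g in range(G):
        sl = tmpl.group_slices[g]
        H[sl, sl] = block[g]
    return F, grad, H


def _value_batched(x: np.ndarray, tmpl: _Template, moments: GroupMoments):
    """Stacked-group discrepancy value only (line searches)."""
    G = moments.n_groups
    p = moments.p
    nref = tmpl.group_slices[0].stop
    xg = np.asarray(x, dtype=float).reshape(G, nref)
    ix = tmpl._idx[0]
    lam = np.zeros((G, p, tmpl.spec.m))
    lam[:, ix["load_i"], ix["load_j"]] = xg[:, ix["load_t"]]
    psi = np.broadcast_to(np.eye(tmpl.spec.m), (G,) + (tmpl.spec.m,) * 2).copy()
    psi[:, ix["fc_i"], ix["fc_j"]] = xg[:, ix["fc_t"]]
    psi[:, ix["fc_j"], ix["fc_i"]] = xg[:, ix["fc_t"]]
    theta = np.zeros((G, p, p))
    theta[:, ix["rv_i"], ix["rv_i"]] = xg[:, ix["rv_t"]]
    theta[:, ix["rc_i"], ix["rc_j"]] = xg[:, ix["rc_t"]]
    theta[:, ix["rc_j"], ix["rc_i"]] = xg[:, ix["rc_t"]]
    sigma = lam @ psi @ lam.transpose(0, 2, 1) + theta
    try:
        L = np.linalg.cholesky((sigma + sigma.transpose(0, 2, 1)) / 2.0)
    except np.linalg.LinAlgError:
        return _PENALTY
    logdets = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    inv = np.linalg.inv(sigma)
    S = np.stack(moments.covs)
    w = np.array(moments.ns, dtype=float) / moments.total_n
    return float(
        np.sum(
            w
            * (
                logdets
                - np.array([moments.logdet(g) for g in range(G)])
                + np.einsum("gij,gij->g", S, inv)
                - p
            )
        )
    )


def _value_grad_info(tmpl: _Template, x: np.ndarray, moments: GroupMoments):
    """(F, dF/dx, expected Hessian of F) in one pass over the groups."""
    if tmpl.homogeneous and moments.n_groups > 1:
        return _value_grad_info_batched(tmpl, x, moments)
    N = moments.total_n
    p = moments.p
    F = 0.0
    grad = np.zeros(tmpl.n_params)
    H = np.zeros((tmpl.n_params, tmpl.n_params))
    for g in range(moments.n_groups):
        sigma, d = _sigma_and_derivs(tmpl, x, g)
        inv, logdet = _safe_inv_logdet(sigma)
        if inv is None:
            return _PENALTY, grad, H
        S = moments.covs[g]
        w = moments.ns[g] / N
        F += w * (logdet - moments.logdet(g) + float(np.sum(S * inv)) - p)
        W = inv - inv @ S @ inv
        sl = tmpl.group_slices[g]
        grad[sl] = w * np.tensordot(d, W, axes=([1, 2], [0, 1]))
        B = np.einsum("ij,tjk,kl->til", inv, d, inv)
        block = np.tensordot(B, d, axes=([1, 2], [1, 2]))
        H[sl, sl] = w * (block + block.T) / 2.0
    return F, grad, H


@dataclass
class FitResult:
    """Result of a multigroup ML fit."""

    spec: ModelSpec
    moments: GroupMoments
    estimates: dict  # ParameterRef -> value
    x: np.ndarray  # free-parameter vector, canonical order
    fmin: float
    T: float  # chi-square statistic, N * fmin
    df: int
    p_value: float
    implied: list[np.ndarray]
    gradient: np.ndarray
    converged: bool
    n_iter: int
    heywood: list[ParameterRef] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.moments.n_groups

    @property
    def total_n(self) -> int:
        return self.moments.total_n

    def estimate(self, ref: ParameterRef) -> float:
        return self.estimates[ref]


def fit(
    spec: ModelSpec,
    moments: GroupMoments,
    start: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit a multigroup CFA by maximum likelihood.

    Parameters
    ----------
    spec
        Model pattern; its group count must match the moments.
    moments
        Per-group covariance matrices and sample sizes.
    start
        Optional warm-start parameter vector (canonical order), e.g. the
        solution of a fit to similar data; defaults to heuristic values.
    gtol
        Convergence criterion: infinity-norm of dF/dtheta.
    """
    if spec.n_groups != moments.n_groups:
        raise ValueError(
            f"spec has {spec.n_groups} groups but moments have {moments.n_groups}"
        )
    if spec.indicators != moments.names:
        raise ValueError(
            "indicator names/order mismatch between spec and moments: "
            f"{spec.indicators} vs {moments.names}"
        )
    df = spec.df()
    if df < 0:
        raise ValueError(f"negative degrees of freedom ({df}): model not identified")

    tmpl = _Template(spec)
    x = tmpl.start_values(moments) if start is None else np.array(start, dtype=float)
    F, grad, H = _value_grad_info(tmpl, x, moments)
    if F >= _PENALTY:  # e.g. a warm start left the PD region
        x = tmpl.start_values(moments)
        F, grad, H = _value_grad_info(tmpl, x, moments)

    converged = False
    n_iter = 0
    msgs: list[str] = []
    eye = np.eye(tmpl.n_params)
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) <= gtol:
            converged = True
            break
        try:
            # small ridge keeps scoring steps defined near singular information
            step = np.linalg.solve(H + 1e-10 * eye, -grad)
        except np.linalg.LinAlgError:
            step = -grad
        value = (
            _value_batched
            if tmpl.homogeneous and moments.n_groups > 1
            else fml_discrepancy
        )
        alpha = 1.0
        for _ in range(30):
            F_new = value(x + alpha * step, tmpl, moments)
            if F_new < F + 1e-14:
                break
            alpha *= 0.5
        else:
            break  # scoring stalled; hand over to quasi-Newton polish
        x = x + alpha * step
        F, grad, H = _value_grad_info(tmpl, x, moments)

    if not converged and np.max(np.abs(grad)) > gtol:
        res = optimize.minimize(
            lambda v: _value_and_grad(tmpl, v, moments),
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol * 0.1, "ftol": 1e-14},
        )
        if res.fun <= F:
            x, F = res.x, res.fun
            _, grad = _value_and_grad(tmpl, x, moments)
        converged = bool(np.max(np.abs(grad)) <= max(gtol, 1e-5))
        if not converged:
            msgs.append(
                f"non-convergence: gradient inf-norm {np.max(np.abs(grad)):.2e} "
                f"after {n_iter} scoring iterations + L-BFGS-B polish"
            )

    estimates = {ref: float(v) for ref, v in zip(tmpl.refs, x)}
    heywood = [
        ref
        for ref, v in estimates.items()
        if ref.role == "residual_variance" and v < 0
    ]
    if heywood:
        msgs.append(f"Heywood case(s): negative residual variance for {heywood}")
    implied = []
    for g in range(spec.n_groups):
        lam, psi, theta = tmpl.matrices(x, g)
        implied.append(lam @ psi @ lam.T + theta)
    T = max(moments.total_n * F, 0.0)
    p_value = float(stats.chi2.sf(T, df)) if df > 0 else float("nan")
    return FitResult(
        spec=spec,
        moments=moments,
        estimates=estimates,
        x=x,
        fmin=F,
        T=T,
        df=df,
        p_value=p_value,
        implied=implied,
        gradient=grad,
        converged=converged,
        n_iter=n_iter,
        heywood=heywood,
        warnings=msgs,
    )


def lrt_compare(fit_restricted: FitResult, fit_full: FitResult):
    """Likelihood-ratio test of nested fits: (delta_chisq, delta_df, p).

    The restricted model's free parameters must be a subset of the full
    model's (checked per group); both fits must use the same moments.
    """
    if fit_restricted.moments is not fit_full.moments and not all(
        np.array_equal(a, b)
        for a, b in zip(fit_restricted.moments.covs, fit_full.moments.covs)
    ):
        raise ValueError("fits compare different moments")
    r, f = fit_restricted.spec, fit_full.spec
    for g in range(r.n_groups):
        if not set(r.free_refs(g)) <= set(f.free_refs(g)):
            raise ValueError("models are not nested: restricted free set is not "
                             "a subset of the full free set")
    d_chi = max(fit_restricted.T - fit_full.T, 0.0)
    d_df = fit_restricted.df - fit_full.df
    p = float(stats.chi2.sf(d_chi, d_df)) if d_df > 0 else 1.0
    return d_chi, d_df, p
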