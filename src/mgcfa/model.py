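"""Symbolic structure of a multigroup confirmatory factor analysis model.

A model is defined over ``p`` observed indicators and ``m`` common factors.
Per group the free parameters are a subset of:

* factor loadings  ``Lambda[i, k]`` (indicator i on factor k),
* residual variances ``Theta[i, i]`` (always free),
* residual covariances ``Theta[i, j]``, i < j (fixed to 0 unless freed),
* factor covariances ``Psi[k, l]``, k < l (always free),

with factor variances ``Psi[k, k]`` fixed to 1 for identification, so that
all on-target loadings can be estimated in every group.  No cross-group
equality constraints exist anywhere: a *configural* model shares only the
pattern of fixed and free parameters across groups, never their values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ALL_GROUPS",
    "ParameterRef",
    "ModelSpec",
    "PopulationModel",
    "build_configural_spec",
    "candidate_constraints",
    "free_parameters",
    "implied_covariance",
    "parse_model",
    "ModelSyntaxError",
]

#: Sentinel group index meaning "this parameter identity in every group".
ALL_GROUPS = -1

_ROLES = (
    "loading",
    "residual_variance",
    "residual_covariance",
    "factor_variance",
    "factor_covariance",
)


@dataclass(frozen=True, order=True)
class ParameterRef:
    """A single model parameter (or a cross-group identity when group=ALL_GROUPS).

    ``row``/``col`` are integer indices: for a loading, (indicator, factor);
    for residual (co)variances, indicator indices; for factor (co)variances,
    factor indices.  Covariances are stored canonically with ``row < col``.
    """

    role: str
    row: int
    col: int
    group: int = ALL_GROUPS

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown parameter role {self.role!r}")
        if self.role in ("residual_covariance", "factor_covariance") and not (
            self.row < self.col
        ):
            raise ValueError(
                f"{self.role} must be stored with row < col, got "
                f"({self.row}, {self.col})"
            )

    def identity(self) -> "ParameterRef":
        """The group-agnostic identity of this parameter."""
        return replace(self, group=ALL_GROUPS)

    def in_group(self, g: int) -> "ParameterRef":
        return replace(self, group=g)


def _canonical_key(ref: ParameterRef) -> tuple:
    # loadings first (by indicator then factor), then residual covariances
    # (row-major); used for deterministic candidate ordering and tie-breaks.
    role_order = {
        "loading": 0,
        "residual_covariance": 1,
        "residual_variance": 2,
        "factor_covariance": 3,
        "factor_variance": 4,
    }
    return (role_order[ref.role], ref.row, ref.col)


@dataclass
class ModelSpec:
    """A multigroup CFA pattern: which parameters are free, per group.

    Attributes
    ----------
    factor_map
        Ordered mapping factor name -> list of on-target indicator names.
    indicators
        All indicator names in canonical (first appearance) order.
    n_groups
        Number of groups.
    loading_free
        Boolean array (G, p, m); True where the loading is estimated.
    rescov_free
        Boolean array (G, p, p); True above the diagonal where a residual
        covariance is estimated.  Diagonal ignored (variances always free).
    """

    factor_map: dict[str, list[str]]
    indicators: list[str]
    n_groups: int
    loading_free: np.ndarray
    rescov_free: np.ndarray

    # -- basic dimensions ------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.indicators)

    @property
    def m(self) -> int:
        return len(self.factor_map)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factor_map)

    def indicator_index(self, name: str) -> int:
        return self.indicators.index(name)

    # -- parameter enumeration -------------------------------------------
    def free_refs(self, group: int) -> list[ParameterRef]:
        """Free parameters of one group, in canonical order.

        Order: loadings (by indicator, then factor), residual variances,
        residual covariances (row-major), factor covariances.
        """
        p, m = self.p, self.m
        refs: list[ParameterRef] = []
        for i in range(p):
            for k in range(m):
                if self.loading_free[group, i, k]:
                    refs.append(ParameterRef("loading", i, k, group))
        for i in range(p):
            refs.append(ParameterRef("residual_variance", i, i, group))
        for i in range(p):
            for j in range(i + 1, p):
                if self.rescov_free[group, i, j]:
                    refs.append(ParameterRef("residual_covariance", i, j, group))
        for k in range(m):
            for l in range(k + 1, m):
                refs.append(ParameterRef("factor_covariance", k, l, group))
        return refs

    def n_free(self, group: int) -> int:
        return (
            int(self.loading_free[group].sum())
            + self.p
            + int(np.triu(self.rescov_free[group], 1).sum())
            + self.m * (self.m - 1) // 2
        )

    def df(self) -> int:
        """Model degrees of freedom: moments minus free parameters, summed."""
        moments = self.p * (self.p + 1) // 2
        return sum(moments - self.n_free(g) for g in range(self.n_groups))

    def is_free(self, ref: ParameterRef) -> bool:
        g = ref.group
        if ref.role == "loading":
            return bool(self.loading_free[g, ref.row, ref.col])
        if ref.role == "residual_variance":
            return True
        if ref.role == "residual_covariance":
            return bool(self.rescov_free[g, ref.row, ref.col])
        if ref.role == "factor_covariance":
            return True
        return False  # factor_variance: fixed at 1

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            factor_map={k: list(v) for k, v in self.factor_map.items()},
            indicators=list(self.indicators),
            n_groups=self.n_groups,
            loading_free=self.loading_free.copy(),
            rescov_free=self.rescov_free.copy(),
        )


def build_configural_spec(
    factor_map: dict[str, list[str]], n_groups: int
) -> ModelSpec:
    """Build a simple-structure configural model.

    Every indicator loads on exactly one factor; all cross-loadings and
    residual covariances are fixed to zero; factor variances are fixed to 1
    and factor covariances are free, in every group.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    indicators: list[str] = []
    owner: dict[str, str] = {}
    for fac, inds in factor_map.items():
        if len(inds) < 1:
            raise ValueError(f"factor {fac!r} has no indicators")
        for ind in inds:
            if ind in owner:
                raise ValueError(
                    f"indicator {ind!r} assigned to both {owner[ind]!r} and {fac!r}"
                )
            owner[ind] = fac
            indicators.append(ind)
    p, m = len(indicators), len(factor_map)
    loading_free = np.zeros((n_groups, p, m), dtype=bool)
    for k, (fac, inds) in enumerate(factor_map.items()):
        for ind in inds:
            loading_free[:, indicators.index(ind), k] = True
    rescov_free = np.zeros((n_groups, p, p), dtype=bool)
    return ModelSpec(
        factor_map={k: list(v) for k, v in factor_map.items()},
        indicators=indicators,
        n_groups=n_groups,
        loading_free=loading_free,
        rescov_free=rescov_free,
    )


def candidate_constraints(spec: ModelSpec) -> list[ParameterRef]:
    """All fixed-to-zero cross-loadings and residual covariances.

    Returned as group-agnostic identities (``group=ALL_GROUPS``) in
    deterministic canonical order: loadings by (indicator, factor), then
    residual covariances by (row, col).  Candidates never include factor
    covariances or the fixed unit factor variances.  Only parameters fixed
    in *every* group are candidates.
    """
    p, m = spec.p, spec.m
    out: list[ParameterRef] = []
    for i in range(p):
        for k in range(m):
            if not spec.loading_free[:, i, k].any():
                out.append(ParameterRef("loading", i, k, ALL_GROUPS))
    for i in range(p):
        for j in range(i + 1, p):
            if not spec.rescov_free[:, i, j].any():
                out.append(ParameterRef("residual_covariance", i, j, ALL_GROUPS))
    return out


def free_parameters(
    spec: ModelSpec, ref: ParameterRef, groups: list[int] | None = None
) -> ModelSpec:
    """Return a new spec with ``ref`` freed in the given groups (default all).

    Raises if the parameter is already free in any named group (a logic
    error in a modification loop) or is not a valid candidate.
    """
    if ref.role not in ("loading", "residual_covariance"):
        raise ValueError(f"cannot free a {ref.role}: not a candidate constraint")
    if groups is None:
        groups = (
            [ref.group] if ref.group != ALL_GROUPS else list(range(spec.n_groups))
        )
    new = spec.copy()
    for g in groups:
        gref = ref.in_group(g)
        if spec.is_free(gref):
            raise ValueError(f"parameter {gref} is already free")
        if ref.role == "loading":
            new.loading_free[g, ref.row, ref.col] = True
        else:
            new.rescov_free[g, ref.row, ref.col] = True
            new.rescov_free[g, ref.col, ref.row] = True
    return new


# ---------------------------------------------------------------------------
# Numeric population models


@dataclass
class PopulationModel:
    """A ModelSpec plus numeric values for every parameter, per group.

    ``loadings[g]`` is (p, m), ``psi[g]`` is (m, m), ``theta[g]`` is (p, p);
    the implied covariance of group g is Lambda Psi Lambda' + Theta.
    """

    spec: ModelSpec
    loadings: np.ndarray  # (G, p, m)
    psi: np.ndarray  # (G, m, m)
    theta: np.ndarray  # (G, p, p)

    def implied_covariance(self, group: int) -> np.ndarray:
        return implied_covariance(
            self.loadings[group], self.psi[group], self.theta[group]
        )

    @property
    def n_groups(self) -> int:
        return self.spec.n_groups


def implied_covariance(
    loadings: np.ndarray, psi: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Model-implied covariance Sigma = Lambda Psi Lambda' + Theta."""
    lam = np.asarray(loadings, dtype=float)
    sigma = lam @ np.asarray(psi, dtype=float) @ lam.T + np.asarray(
        theta, dtype=float
    )
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# Model syntax


class ModelSyntaxError(ValueError):
    """Raised for malformed model syntax, with a line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def parse_model(text: str, n_groups: int = 1) -> ModelSpec:
    """Parse a plain-text factor model into a ModelSpec.

    Grammar (one statement per line, ``#`` starts a comment)::

        visual =~ x1 + x2 + x3     # factor definition
        x7 ~~ x8                   # freed residual covariance (all groups)

    An indicator repeated under a second factor frees that cross-loading.
    The first factor listing an indicator is its home factor; parsing is
    case-sensitive.
    """
    factor_map: dict[str, list[str]] = {}
    cross: list[tuple[str, str, int]] = []  # (factor, indicator, line)
    rescov: list[tuple[str, str, int]] = []
    owner: dict[str, str] = {}
    any_statement = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, _, rhs = line.partition("=~")
            fac = lhs.strip()
            if not fac or not fac.isidentifier():
                raise ModelSyntaxError(f"bad factor name {lhs.strip()!r}", lineno)
            if fac in factor_map:
                raise ModelSyntaxError(f"duplicate factor {fac!r}", lineno)
            inds = [t.strip() for t in rhs.split("+")]
            if not inds or any(not t for t in inds):
                raise ModelSyntaxError("empty indicator in '+' list", lineno)
            factor_map[fac] = []
            for ind in inds:
                if not ind.isidentifier():
                    raise ModelSyntaxError(f"bad indicator name {ind!r}", lineno)
                if ind in owner:
                    cross.append((fac, ind, lineno))  # cross-loading, freed
                else:
                    owner[ind] = fac
                    factor_map[fac].append(ind)
            any_statement = True
        elif "~~" in line:
            lhs, _, rhs = line.partition("~~")
            a, b = lhs.strip(), rhs.strip()
            if not a.isidentifier() or not b.isidentifier():
                raise ModelSyntaxError(f"bad covariance statement {line!r}", lineno)
            rescov.append((a, b, lineno))
            any_statement = True
        else:
            raise ModelSyntaxError(f"unrecognized statement {line!r}", lineno)
    if not any_statement:
        raise ModelSyntaxError("empty model: no statements found", 1)
    if not factor_map:
        raise ModelSyntaxError("no factor ('=~') definitions found", 1)
    spec = build_configural_spec(factor_map, n_groups)
    for fac, ind, lineno in cross:
        k = spec.factor_names.index(fac)
        i = spec.indicator_index(ind)
        spec.loading_free[:, i, k] = True
    for a, b, lineno in rescov:
        for name in (a, b):
            if name not in spec.indicators:
                raise ModelSyntaxError(
                    f"unknown indicator {name!r} in covariance", lineno
                )
        i, j = sorted((spec.indicator_index(a), spec.indicator_index(b)))
        if i == j:
            raise ModelSyntaxError(
                "residual variances are always free; '~~' needs two distinct "
                "indicators",
                lineno,
            )
        spec.rescov_free[:, i, j] = True
        spec.rescov_free[:, j, i] = True
    return spec
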