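import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgcfa import (
    ALL_GROUPS,
    ParameterRef,
    build_configural_spec,
    candidate_constraints,
    free_parameters,
    implied_covariance,
    parse_model,
)
from mgcfa.model import ModelSyntaxError

from conftest import HS_FACTOR_MAP


@pytest.mark.parametrize(
    "factor_map, n_groups, free_per_group, total_df",
    [
        (HS_FACTOR_MAP, 2, 21, 48),
        ({"f1": ["a", "b", "c"], "f2": ["d", "e", "f"]}, 4, 13, 32),
        ({"f": ["a", "b", "c"]}, 1, 6, 0),  # just-identified
    ],
)
def test_configural_df_counting(factor_map, n_groups, free_per_group, total_df):
    spec = build_configural_spec(factor_map, n_groups)
    assert spec.n_free(0) == free_per_group
    assert spec.df() == total_df


def test_configural_spec_rejects_bad_maps():
    with pytest.raises(ValueError, match="assigned to both"):
        build_configural_spec({"f1": ["a", "b"], "f2": ["a"]}, 2)
    with pytest.raises(ValueError, match="no indicators"):
        build_configural_spec({"f1": ["a"], "f2": []}, 2)


@pytest.mark.parametrize(
    "factor_map, n_groups, n_identities, n_univariate",
    [
        (HS_FACTOR_MAP, 2, 54, 108),  # 18 cross-loadings + 36 residual covs
        ({"f1": ["a", "b", "c"], "f2": ["d", "e", "f"]}, 4, 21, 84),
        ({"f": ["a", "b", "c"]}, 1, 3, 3),  # no cross-loadings possible
    ],
)
def test_candidate_counts(factor_map, n_groups, n_identities, n_univariate):
    spec = build_configural_spec(factor_map, n_groups)
    cands = candidate_constraints(spec)
    assert len(cands) == n_identities
    assert len(cands) * n_groups == n_univariate
    # deterministic canonical order: all loadings before all covariances
    roles = [c.role for c in cands]
    if "loading" in roles:
        assert roles.index("residual_covariance") == roles.count("loading")


def test_parameter_space_partitions(spec6):
    """Free params, candidates and fixed unit factor variances tile the whole
    parameter space with no overlap."""
    p, m, G = spec6.p, spec6.m, spec6.n_groups
    cands = candidate_constraints(spec6)
    for g in range(G):
        free = set(spec6.free_refs(g))
        cand_g = {c.in_group(g) for c in cands}
        fixed_psi = {ParameterRef("factor_variance", k, k, g) for k in range(m)}
        assert not free & cand_g
        n_total = p * m + p + p * (p - 1) // 2 + m * (m + 1) // 2
        assert len(free) + len(cand_g) + len(fixed_psi) == n_total


@st.composite
def factor_maps(draw):
    m = draw(st.integers(1, 3))
    sizes = [draw(st.integers(1, 4)) for _ in range(m)]
    names = iter(f"x{i}" for i in range(sum(sizes)))
    return {f"f{k}": [next(names) for _ in range(sizes[k])] for k in range(m)}


@settings(max_examples=40, deadline=None, derandomize=True)
@given(factor_map=factor_maps(), n_groups=st.integers(1, 4))
def test_df_and_candidate_identities_hold_for_any_structure(
    factor_map, n_groups
):
    """Moment-counting identities hold for arbitrary simple structures:
    df = G*[p(p+1)/2 - free] and candidates = fixed cross-loadings plus all
    residual covariances."""
    spec = build_configural_spec(factor_map, n_groups)
    p, m = spec.p, spec.m
    free = p + p + m * (m - 1) // 2  # loadings + resvar + factor covs
    assert spec.df() == n_groups * (p * (p + 1) // 2 - free)
    cands = candidate_constraints(spec)
    assert len(cands) == p * m - p + p * (p - 1) // 2
    assert len(set(cands)) == len(cands)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_implied_covariance_symmetric_psd_for_valid_parameters(seed):
    rng = np.random.default_rng(seed)
    p, m = 6, 2
    lam = rng.uniform(-1, 1, (p, m))
    rho = rng.uniform(-0.9, 0.9)
    psi = np.array([[1.0, rho], [rho, 1.0]])
    theta = np.diag(rng.uniform(0.05, 1.5, p))
    sigma = implied_covariance(lam, psi, theta)
    assert np.array_equal(sigma, sigma.T)
    assert np.linalg.eigvalsh(sigma).min() > 0


def test_implied_covariance_matches_double_loop_oracle():
    rng = np.random.default_rng(3)
    p, m = 5, 2
    lam = rng.normal(size=(p, m))
    psi = np.array([[1.0, 0.3], [0.3, 1.0]])
    theta = np.diag(rng.uniform(0.2, 1.0, p))
    sigma = implied_covariance(lam, psi, theta)
    oracle = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            for k in range(m):
                for l in range(m):
                    oracle[i, j] += lam[i, k] * psi[k, l] * lam[j, l]
            oracle[i, j] += theta[i, j]
    assert np.allclose(sigma, oracle, atol=1e-12)


def test_study_population_implied_moments(population):
    """Unit indicator variances by construction; hand-checked covariances."""
    for g in range(4):
        sigma = population.implied_covariance(g)
        assert np.allclose(np.diag(sigma), 1.0, atol=1e-12)
    s1 = population.implied_covariance(0)
    assert s1[0, 1] == pytest.approx(0.6 * 0.7)  # same-factor indicators
    assert s1[0, 3] == pytest.approx(0.6 * 0.6 * 0.2 + 0.2)  # + residual cov


def test_zero_loadings_imply_theta():
    theta = np.diag([0.5, 1.0, 2.0])
    sigma = implied_covariance(np.zeros((3, 2)), np.eye(2), theta)
    assert np.array_equal(sigma, theta)


def test_free_parameters_reduces_df(hs_spec, spec6):
    ref = ParameterRef("loading", 8, 0, ALL_GROUPS)  # visual -> x9
    assert free_parameters(hs_spec, ref).df() == 46
    both = spec6
    for ref in (
        ParameterRef("residual_covariance", 0, 3, ALL_GROUPS),
        ParameterRef("residual_covariance", 1, 4, ALL_GROUPS),
    ):
        both = free_parameters(both, ref)
    assert both.df() == 24


def test_free_parameters_rejects_already_free(hs_spec):
    with pytest.raises(ValueError, match="already free"):
        free_parameters(hs_spec, ParameterRef("loading", 0, 0, ALL_GROUPS))
    with pytest.raises(ValueError, match="not a candidate"):
        free_parameters(
            hs_spec, ParameterRef("factor_covariance", 0, 1, ALL_GROUPS)
        )


HS_SYNTAX = """\
# classic three-factor mental-ability model
visual  =~ x1 + x2 + x3
textual =~ x4 + x5 + x6
speed   =~ x7 + x8 + x9
"""


def test_parse_model_roundtrip():
    spec = parse_model(HS_SYNTAX, n_groups=2)
    assert spec.factor_map == HS_FACTOR_MAP
    assert spec.df() == 48


def test_parse_model_frees_residual_covariance_and_cross_loading():
    spec = parse_model(HS_SYNTAX + "x7 ~~ x8\n", n_groups=2)
    assert all(spec.rescov_free[g, 6, 7] for g in range(2))
    assert spec.df() == 46
    # a cross-loading repeats the indicator inside another factor definition
    spec3 = parse_model(
        "visual =~ x1 + x2 + x3 + x9\nspeed =~ x7 + x8 + x9\n", n_groups=2
    )
    i9 = spec3.indicator_index("x9")
    k_speed = spec3.factor_names.index("speed")
    assert spec3.loading_free[:, i9, k_speed].all()  # freed cross-loading


@pytest.mark.parametrize(
    "text, match",
    [
        ("", "empty model"),
        ("visual = x1 + x2", "unrecognized"),
        ("visual =~ x1\nvisual =~ x2", "duplicate factor"),
        ("f =~ x1 + x2\nx1 ~~ zz", "unknown indicator"),
        ("f =~ x1 + x2\nx1 ~~ x1", "distinct"),
    ],
)
def test_parse_model_errors(text, match):
    with pytest.raises(ModelSyntaxError, match=match):
        parse_model(text, n_groups=2)
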