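import numpy as np
import pytest

from mgcfa import (
    analysis_spec,
    build_configural_spec,
    draw_sample,
    fit,
    moments_from_matrices,
    sample_moments,
    study_population,
)

HS_FACTOR_MAP = {
    "visual": ["x1", "x2", "x3"],
    "textual": ["x4", "x5", "x6"],
    "speed": ["x7", "x8", "x9"],
}


@pytest.fixture(scope="session")
def population():
    return study_population()


@pytest.fixture(scope="session")
def spec6(population):
    """Misspecified configural model of the study: 2 factors, 6 indicators,
    4 groups."""
    return analysis_spec(population)


@pytest.fixture(scope="session")
def hs_spec():
    """Three-factor, nine-indicator, two-group simple-structure model."""
    return build_configural_spec(HS_FACTOR_MAP, n_groups=2)


@pytest.fixture(scope="session")
def pop_moments(population, spec6):
    """The four population covariance matrices treated as samples of n=100."""
    return moments_from_matrices(
        [population.implied_covariance(g) for g in range(4)],
        [100] * 4,
        names=spec6.indicators,
    )


@pytest.fixture(scope="session")
def pop_fit(spec6, pop_moments):
    return fit(spec6, pop_moments)


@pytest.fixture(scope="session")
def sampled(population):
    """One fixed draw of n=100 per group plus its moments and configural fit."""
    rng = np.random.default_rng(20240811)
    data = draw_sample(population, 100, rng)
    moments = sample_moments(data, "group")
    return data, moments


@pytest.fixture(scope="session")
def sampled_fit(spec6, sampled):
    _, moments = sampled
    return fit(spec6, moments)


def two_group_population():
    """First two groups of the study population (for cheaper permutation
    work)."""
    import copy

    pop = study_population()
    pop2 = copy.deepcopy(pop)
    pop2.spec.n_groups = 2
    pop2.spec.loading_free = pop.spec.loading_free[:2]
    pop2.spec.rescov_free = pop.spec.rescov_free[:2]
    pop2.loadings = pop.loadings[:2]
    pop2.psi = pop.psi[:2]
    pop2.theta = pop.theta[:2]
    return pop2
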