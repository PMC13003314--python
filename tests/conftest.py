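import numpy as np
import pytest

from cthmm.model import (
    BetaParams,
    CovariateVector,
    EmissionParams,
    InitialDistribution,
    ModelParams,
    allowed_edges,
)


@pytest.fixture
def structure92():
    return allowed_edges(9, 2)


@pytest.fixture
def structure32():
    return allowed_edges(3, 2)


def random_forward_generator(structure, rng, scale=0.5):
    """Random log-rates ~ N(0, scale) on the allowed edges, intercept only."""
    from cthmm.model import build_generator

    bmat = rng.normal(0.0, scale, (structure.n_edges, 1))
    beta = BetaParams.from_matrix(bmat, structure)
    z = CovariateVector(np.array([1.0]), ("intercept",))
    return build_generator(beta, z, structure)


def random_model(structure, n_features, rng, l_dim=1):
    """Random dimension-consistent parameter bundle for small oracles."""
    m = structure.n_states
    bmat = rng.normal(0.0, 0.5, (structure.n_edges, l_dim))
    beta = BetaParams.from_matrix(bmat, structure)
    means = rng.normal(0.0, 2.0, (m, n_features))
    variances = rng.uniform(0.5, 1.5, (m, n_features))
    pi = rng.dirichlet(np.ones(m))
    return ModelParams(
        structure, beta, EmissionParams(means, variances), InitialDistribution(pi)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
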