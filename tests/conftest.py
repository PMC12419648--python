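import numpy as np
import pytest
import scipy.sparse as sp

from grnsim import (
    ExpressionParams,
    GeneratorParams,
    Grn,
    SimulationConfig,
    generate_network,
    sample_expression_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain3():
    """3-gene activating chain 0 -> 1 -> 2 with deterministic dynamics."""
    grn = Grn(n=3, edges=[(0, 1), (1, 2)], group_of=np.zeros(3, dtype=np.int64))
    beta = sp.csr_matrix(([1.5, 1.5], ([0, 1], [1, 2])), shape=(3, 3))
    params = ExpressionParams(alpha=np.full(3, -1.0), ell=np.full(3, 0.8), beta=beta, s=0.0)
    return grn, params


@pytest.fixture
def small_grn(rng):
    gp = GeneratorParams(n=40, p=0.4, k=4, w=5.0, delta_in=5.0, delta_out=5.0, seed=7)
    return generate_network(gp, np.random.default_rng(7))


@pytest.fixture
def small_system(small_grn):
    params = sample_expression_params(small_grn, np.random.default_rng(8), s=0.0)
    return small_grn, params


@pytest.fixture
def edgeless_params(rng):
    n = 12
    alpha = rng.normal(-1.5, 0.5, n)
    ell = rng.uniform(0.5, 1.0, n)
    return ExpressionParams(alpha=alpha, ell=ell, beta=sp.csr_matrix((n, n)), s=0.0)


@pytest.fixture
def fast_config():
    return SimulationConfig(burn_in=500, check_every=200, t_max=5000, tolerance=1e-4)
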