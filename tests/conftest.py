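import numpy as np
import pytest

from immunoalloc import (
    ModelParams,
    ReserveGrid,
    build_discrete_gaussian,
    solve_stochastic,
)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_grid():
    return ReserveGrid(21)


@pytest.fixture(scope="session")
def coarse_gauss():
    """Small discrete-Gaussian gain model for fast stochastic solves."""
    return build_discrete_gaussian(N=8)


@pytest.fixture(scope="session")
def small_policy(small_grid, coarse_gauss):
    """A solved stochastic policy on a coarse grid, shared across tests."""
    params = ModelParams(M=1.0, gamma=4.0, f=0.5)
    return solve_stochastic(params, small_grid, coarse_gauss, T=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
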