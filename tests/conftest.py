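import numpy as np
import pytest

from normsgame import SimulationParams, init_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """10x10 lattice, short horizon, baseline payoffs."""
    return SimulationParams(n_rows=10, n_cols=10, R=2, T=5, seed=7)


@pytest.fixture
def small_state(small_params, rng):
    return init_grid(small_params, rng)
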