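import numpy as np
import pytest
from hypothesis import settings

import chunknet as ck

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return ck.SessionConfig()


@pytest.fixture
def small_plan(rng):
    """A short recurrent session for fast end-to-end tests."""
    cfg = ck.SessionConfig(n_episodes=6)
    return ck.generate_session(cfg, rng)


@pytest.fixture
def sim_params():
    """The simulation parameter point used throughout the figures."""
    return ck.ModelParams(alpha=0.4, beta=7.0, epsilon=0.0,
                          QP=0.17, J_INC=0.7)


@pytest.fixture
def small_dataset(sim_params, small_plan, rng):
    data, _ = ck.simulate_session(sim_params, small_plan, True, rng,
                                  collect_trace=False)
    return data
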