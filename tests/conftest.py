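import numpy as np
import pytest
from hypothesis import settings

import qhtskit as q

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_screen():
    """A 10-compound simulated primary screen with one planted protectant."""
    cfg = q.SimulationConfig(seed=7, n_compounds=10)
    records, truth = q.simulate_screen(cfg)
    return cfg, records, truth
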