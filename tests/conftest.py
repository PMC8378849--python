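import numpy as np
import pytest

from pupilswitch import RunConfig, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Two short trials: enough structure for unit tests, fast to simulate."""
    return SimConfig(n_trials=2, trial_len_s=20.0)


@pytest.fixture
def run_cfg():
    return RunConfig()
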