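import numpy as np
import pytest

from autoreg.feedback_model import ModelParams
from autoreg.synthetic_data import scenario_presets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hill_params():
    """Reference finite-n parameter set used across the model tests."""
    return ModelParams(beta=1.0, gamma=1.0, K=0.5, n=4, c=2)


@pytest.fixture
def presets():
    return scenario_presets(noise_cv=0.1, n_embryos=50)
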