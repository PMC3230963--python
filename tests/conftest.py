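import numpy as np
import pytest

from segmoment import NoiseModel, dummy_bar_model, human_leg_model


@pytest.fixture
def dummy_model():
    """Calibrated bench-top configuration: end-pivoted uniform bar (3.013 kg,
    77.2 cm) + 52.066 kg block + 11.627 kg board; true moment 116.3018 kg·cm."""
    return dummy_bar_model()


@pytest.fixture
def human_model():
    """Synthetic subject + frame with a 10 kg leg and 388.8 kg·cm true moment."""
    return human_leg_model()


@pytest.fixture
def default_noise():
    return NoiseModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
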