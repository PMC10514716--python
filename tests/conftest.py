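import numpy as np
import pytest

from synaptune.imaging_sim import ReceptiveFieldModel
from synaptune.stimulus import build_tone_block

LEVELS = [40.0, 50.0, 60.0, 70.0, 80.0]


@pytest.fixture(scope="session")
def tone_block():
    """The standard 5-40 kHz, 1/8-octave, 5-level mapping block."""
    return build_tone_block(5000.0, 40000.0, 0.125, LEVELS, seed=7)


@pytest.fixture(scope="session")
def clean_rf_model():
    """A deterministic receptive field (no noise, no repeat jitter)."""
    return ReceptiveFieldModel(noise_sd=0.0, repeat_jitter_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
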