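import numpy as np
import pytest

from eegmusic.recording import EEGRecording
from eegmusic.synth import simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """A 20-s contaminated session with default contamination (seed 7)."""
    return simulate_session(duration_s=20.0, seed=7)


@pytest.fixture
def small_recording(rng):
    return EEGRecording(data=rng.normal(size=(3, 500)), fs=250.0)
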