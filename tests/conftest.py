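import numpy as np
import pytest

from nightcough.detect import SoundEvent
from nightcough.synth import SynthConfig, cough_wave

SR = 16_000


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def synth_config():
    return SynthConfig()


@pytest.fixture
def cough_event(rng, synth_config):
    """One unvoiced synthetic cough wrapped as a detected event."""
    w = cough_wave(0.5, False, SR, rng, amplitude=0.7)
    return SoundEvent(0, len(w), SR, w)


@pytest.fixture
def voiced_cough_event(rng, synth_config):
    w = cough_wave(0.7, True, SR, rng, voiced_f0=150.0, amplitude=0.7)
    return SoundEvent(0, len(w), SR, w)


def make_event(x, sr=SR):
    return SoundEvent(0, len(x), sr, np.asarray(x, dtype=float))
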