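import numpy as np
import pytest

from thermobreath.frame_codec import TemperatureMap
from thermobreath.synthetic import SceneParams, SyntheticBreathParams, simulate_breath_signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_map(rng):
    """Seeded random temperature map in a realistic indoor range."""
    return TemperatureMap(rng.uniform(15.0, 40.0, size=(16, 12)))


@pytest.fixture
def small_scene():
    """Compact scene for fast frame-level tests (geometry scaled down)."""
    return SceneParams(height=72, width=96, face_axes=(20.0, 24.0))


@pytest.fixture
def clean_signal():
    """Noiseless, drift-free 0.3 Hz (18 BPM) breathing signal, 60 s at 25 Hz."""
    params = SyntheticBreathParams(f_rr=0.3, noise_sd=0.0, drift_amp=0.0, seed=0)
    return simulate_breath_signal(params)
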