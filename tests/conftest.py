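import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coordstab.preprocess import SampledSignal

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_period100():
    """Noiseless sine with period exactly 100 samples, 2500 samples total."""
    return np.sin(2 * np.pi * np.arange(2500) / 100)


@pytest.fixture
def sine_signal():
    """1 Hz sine sampled at 100 Hz for 20 s, amplitude 10 mm."""
    t = np.arange(2000) / 100
    return SampledSignal(10 * np.sin(2 * np.pi * t), rate=100.0, kind="position_SI")
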