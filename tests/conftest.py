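import numpy as np
import pytest

from evoseizure.genotype import GeneDomains

FS = 256.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def domains():
    return GeneDomains()


def sinusoid(freq_hz: float, amplitude: float = 1.0, seconds: float = 5.0,
             fs: float = FS, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(seconds * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


@pytest.fixture
def make_sinusoid():
    return sinusoid
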