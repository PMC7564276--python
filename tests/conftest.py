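import numpy as np
import pytest

from restconn import BandSpec, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alpha_band():
    return BandSpec("alpha", 7.5, 12.5)


@pytest.fixture
def fs():
    return 256.0


def make_recording(data, fs=256.0, labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(tuple(labels), fs, data)


@pytest.fixture
def sinusoid():
    def _make(freq, fs=256.0, duration=10.0, phase=0.0):
        t = np.arange(int(duration * fs)) / fs
        return np.cos(2 * np.pi * freq * t + phase), t

    return _make
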