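import numpy as np
import pytest

from scalodx import GeneratorConfig, Segment, detrend


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cosine_segment():
    """A detrended 5 Hz cosine, 5 s at 250 Hz."""
    fs = 250.0
    t = np.arange(1250) / fs
    return detrend(Segment(samples=np.cos(2 * np.pi * 5.0 * t), fs=fs))


def make_segment(samples, fs=250.0, **kw):
    return Segment(samples=np.asarray(samples, dtype=float), fs=fs, **kw)


@pytest.fixture
def make_seg():
    return make_segment
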