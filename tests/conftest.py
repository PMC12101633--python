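import numpy as np
import pytest

from trfseg import GaborKernel, LagWindow, PulseStimulusConfig, SegmentPair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lag_window():
    return LagWindow(0.0, 0.4, 128.0)


@pytest.fixture
def kernel():
    return GaborKernel()


@pytest.fixture
def pulse_cfg():
    return PulseStimulusConfig()


@pytest.fixture
def small_segments(rng):
    """Ten 2-s segments of 2-band stimulus and 3-channel response at 64 Hz."""
    fs = 64.0
    segs = []
    for _ in range(10):
        stim = rng.standard_normal((128, 2))
        w = rng.standard_normal((5, 2, 3))
        resp = np.zeros((128, 3))
        for lag in range(5):
            for b in range(2):
                shifted = np.zeros(128)
                shifted[lag:] = stim[: 128 - lag, b]
                resp += shifted[:, None] * w[lag, b][None, :]
        resp += 0.1 * rng.standard_normal((128, 3))
        segs.append(SegmentPair(stim, resp, fs))
    return segs
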