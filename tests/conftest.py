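import numpy as np
import pytest

from accelmix import RunConfig, ScalarSeries, TriaxialTrace


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(xyz, rate=200.0, rid="t"):
    return TriaxialTrace(sample_rate_hz=rate, samples=np.asarray(xyz, float),
                         recording_id=rid)


def make_index(values, rate=10.0):
    return ScalarSeries(sample_rate_hz=rate, values=np.asarray(values, float),
                        kind="acceleration_index")


@pytest.fixture
def sine_trace():
    """5 Hz unit-amplitude sine on the x axis, 60 s at 200 Hz."""
    t = np.arange(12000) / 200.0
    xyz = np.zeros((12000, 3))
    xyz[:, 0] = np.sin(2 * np.pi * 5.0 * t)
    return make_trace(xyz)
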