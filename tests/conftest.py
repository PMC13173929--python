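import numpy as np
import pytest

from termwalk import Arena, Trajectory


def make_traj(xy, rate_hz=5.0, **kwargs):
    xy = np.asarray(xy, dtype=float)
    times = np.arange(xy.shape[0]) / rate_hz
    return Trajectory(times=times, xy=xy, rate_hz=rate_hz, **kwargs)


@pytest.fixture
def traj_factory():
    return make_traj


@pytest.fixture
def arena():
    return Arena()


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
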