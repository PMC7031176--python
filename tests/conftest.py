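import numpy as np
import pytest

from mhrv.io import RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_rr():
    """1000 intervals of exactly 100 ms."""
    return RRSeries.from_intervals(np.full(1000, 100.0), animal_id="const")


@pytest.fixture
def alternating_rr():
    """1000 intervals alternating 90/110 ms."""
    nn = np.tile([90.0, 110.0], 500)
    return RRSeries.from_intervals(nn, animal_id="alt")


@pytest.fixture
def gaussian_rr(rng):
    """Realistic jittered series: ~100 ms mean, 5 ms SD, 2000 beats."""
    nn = rng.normal(100.0, 5.0, 2000)
    return RRSeries.from_intervals(nn, animal_id="gauss")


def write_csv(path, text):
    path.write_text(text)
    return path
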