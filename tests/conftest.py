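import numpy as np
import pytest
import threadpoolctl

from vitalradar import RadarConfig


@pytest.fixture(scope="session", autouse=True)
def single_threaded_blas():
    """Pin BLAS to one thread: results are then independent of core count."""
    with threadpoolctl.threadpool_limits(limits=1):
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_radar():
    """A short, low-rate acquisition used to keep unit tests fast."""
    return RadarConfig(fs_hz=20.0, n_samples=201)
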