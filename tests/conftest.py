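import numpy as np
import pytest

from unistdp import load_preset
from unistdp.stp import STPParams, SpikeTrain


@pytest.fixture(scope="session")
def preset():
    """The shipped young-rat visual-cortex rule constants."""
    return load_preset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def poisson_train(rng, rate_hz=20.0, duration_s=1.0, id=""):
    """Homogeneous Poisson spike train (seconds)."""
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    # enforce strict increase (merge-collisions are measure-zero but float-possible)
    times = np.unique(times)
    return SpikeTrain(times=times, id=id)


@pytest.fixture
def stp_defaults():
    return STPParams(D=200.0, F=50.0, P_baseline=0.5)
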