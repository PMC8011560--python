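import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210210)


@pytest.fixture
def flat_grid():
    """A 0-10 min grid at 0.005 min steps."""
    return np.arange(0.0, 10.0 + 1e-12, 0.005)


def gaussian(x, height, rt, width):
    return height * np.exp(-(((x - rt) / width) ** 2))


@pytest.fixture(scope="session")
def small_batch():
    """A compact simulated batch for unit tests: 4 samples, 3 channels."""
    from mrmscreen.synthgen import SimConfig, default_target_peaks, simulate_batch

    cfg = SimConfig(
        n_samples=4,
        n_channels=3,
        rt_stop=20.0,
        peaks=default_target_peaks(3, per_channel=2),
        standard_rts=(3.0, 10.0, 18.0),
        seed=7,
    )
    return simulate_batch(cfg)
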