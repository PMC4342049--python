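import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_effect_sim():
    """One simulated day with canonical stimulation and a strong effect;
    shared by tests that only need a realistic trajectory."""
    from dbsmotor.synthetic import make_effect_config, simulate

    return simulate(make_effect_config(seed=11, n_days=1))


@pytest.fixture(scope="session")
def small_effect_processes(small_effect_sim):
    from dbsmotor.motor_processes import extract_processes

    return extract_processes(small_effect_sim.recording)


def make_ar1(rng, n, phi, sigma=1.0, burn=500):
    """AR(1) sample after burn-in (approximately stationary start)."""
    from scipy.signal import lfilter

    e = rng.normal(0.0, sigma, n + burn)
    return lfilter([1.0], [1.0, -phi], e)[burn:]


@pytest.fixture
def ar1():
    return make_ar1
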