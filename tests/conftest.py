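import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmaquant import simulate as tsim

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small two-marker simulation for fast imaging tests."""
    return tsim.SimulationParams(
        n_patients=12,
        markers=("NLRP6", "IL18"),
        log_hazard_ratios={"NLRP6_low": np.log(1.72), "IL18_low": np.log(1.68)},
        spot_radius_px=40,
        n_nuclei_per_spot=60,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_params):
    return tsim.generate_cohort(small_params)
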