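import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """Small lattice for fast simulator unit tests."""
    from sirswitch.sim import SimConfig
    return SimConfig(L=40, N_sir_total=20, locus_window=(2, 10),
                     t_burn=1.0, t_record=10.0)
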