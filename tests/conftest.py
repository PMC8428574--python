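import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_task():
    """Three subjects: events at t=1 and t=2, censoring at t=3."""
    from survkit import make_task

    return make_task([[1.0], [2.0], [3.0]], [1, 2, 3], [1, 1, 0])


@pytest.fixture
def ph_task():
    """Moderate proportional-hazards simulation with known truth."""
    from survkit import SimConfig, simulate_surv

    cfg = SimConfig(n=400, p=2, beta=(0.5, -0.5), model="ph",
                    censoring=("exponential", 0.3), seed=20)
    return simulate_surv(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
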