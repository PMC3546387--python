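import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tvcsim import BaselineHazard
from tvcsim.power_study import synth_population

settings.register_profile(
    "tvcsim",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("tvcsim")


BASELINES = [
    BaselineHazard.exponential(0.5),
    BaselineHazard.weibull(0.001, 0.6),
    BaselineHazard.weibull(1.0, 2.0),
    BaselineHazard.gompertz(0.2, 0.1),
    BaselineHazard.gompertz(0.2, -0.05),
    BaselineHazard.gompertz(0.2, 0.0),
]


@pytest.fixture(params=BASELINES, ids=lambda b: f"{b.family}-lam{b.lam}")
def baseline(request) -> BaselineHazard:
    return request.param


@pytest.fixture(scope="session")
def small_population():
    """10k-row synthetic cohort shared across fitting tests."""
    return synth_population(10_000, np.random.SeedSequence(2024))
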