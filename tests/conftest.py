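import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lifetraj import (
    ScenarioParams,
    SimulationSettings,
    build_design,
    simulate_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """20 individuals with moderate state dependence and heterogeneity."""
    params = ScenarioParams(gamma=0.3, sigma_phi=0.5, sigma_repro=0.8)
    settings_ = SimulationSettings(n_individuals=20, max_occasions=20)
    return simulate_panel(params, settings_, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_design(small_panel):
    return build_design(small_panel)


@pytest.fixture(scope="session")
def null_panel():
    """1,000 individuals, no state dependence, negligible heterogeneity."""
    params = ScenarioParams(gamma=0.0)
    settings_ = SimulationSettings(n_individuals=1000)
    return simulate_panel(params, settings_, np.random.default_rng(99))
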