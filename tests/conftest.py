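import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from sibnet.synthdata import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale study configuration with a strong planted effect."""
    return SimulationConfig(
        n_pairs_large=8,
        n_pairs_small=10,
        n_genes=80,
        n_risk_genes=15,
        lambda_background=30.0,
        lambda_effect=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
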