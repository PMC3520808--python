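import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfcentiles import SimConfig, filter_registry, simulate_registry
from cfcentiles.simulate import CountrySpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def unselected_config(**kwargs) -> SimConfig:
    """Config with every country reporting unselected single visits, so the
    record-level distribution matches the closed-form oracle exactly."""
    kwargs.setdefault(
        "country_labels",
        (
            CountrySpec("France", "FR", 0.5, False),
            CountrySpec("Germany", "DE", 0.5, False),
        ),
    )
    kwargs.setdefault("visits_per_year", 1)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_patients_per_sex=400, seed=7)


@pytest.fixture(scope="session")
def small_registry(small_config):
    return simulate_registry(small_config)


@pytest.fixture(scope="session")
def fev1_registry(small_registry):
    return filter_registry(small_registry, "fev1")


@pytest.fixture(scope="session")
def medium_oracle_setup():
    """A 5000/sex pure-unselected registry plus its generating config, for
    coverage / recovery / rank-calibration checks against the closed form."""
    config = unselected_config(n_patients_per_sex=5000, seed=42)
    registry = filter_registry(simulate_registry(config), "fev1")
    return config, registry


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
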