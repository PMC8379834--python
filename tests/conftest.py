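import pytest
from hypothesis import HealthCheck, settings

from geolink_coverage.config import (
    BehaviorConfig,
    ExperimentConfig,
    LandscapeConfig,
)
from geolink_coverage.landscape import generate_landscape, simulate_careseeking

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def small_landscape_config(**overrides) -> LandscapeConfig:
    """A reduced landscape used where full study size is unnecessary."""
    defaults = dict(
        n_households_by_stratum={"rural": 60, "urban": 80},
        n_providers={
            "govt_hospital": {"rural": 0, "urban": 1},
            "govt_health_center_post": {"rural": 3, "urban": 2},
            "govt_cba_fieldworker": {"rural": 6, "urban": 2},
            "pvt_hospital_clinic": {"rural": 0, "urban": 1},
            "pharmacy": {"rural": 1, "urban": 1},
            "shop_market": {"rural": 3, "urban": 4},
            "traditional_faith": {"rural": 2, "urban": 1},
        },
    )
    defaults.update(overrides)
    return LandscapeConfig(**defaults)


@pytest.fixture(scope="session")
def default_landscape():
    return generate_landscape(LandscapeConfig(), seed=7)


@pytest.fixture(scope="session")
def default_events(default_landscape):
    return simulate_careseeking(default_landscape, BehaviorConfig(), seed=5)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(small_landscape_config(), seed=11)


@pytest.fixture(scope="session")
def small_events(small_landscape):
    return simulate_careseeking(small_landscape, BehaviorConfig(), seed=13)


@pytest.fixture()
def small_experiment_config():
    return ExperimentConfig(landscape=small_landscape_config(), n_boot=100)
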