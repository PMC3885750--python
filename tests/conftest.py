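from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hsettings

from pahexposure.datasets import load_default_settings
from pahexposure.population import ParamSpec, PopulationConfig

hsettings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hsettings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_settings():
    s = load_default_settings()
    s.validate()
    return s


def _degenerate(spec: ParamSpec) -> ParamSpec:
    return replace(spec, sd=0.0)


@pytest.fixture(scope="session")
def degenerate_population(default_settings) -> PopulationConfig:
    """Population config with every SD zeroed: deterministic individuals."""
    pop = default_settings.population
    regions = {
        name: replace(
            params,
            **{
                key: _degenerate(getattr(params, key))
                for key in (
                    "ach", "floor_area_m2", "penetration", "time_home_h",
                    "time_work_school_h", "smoking_cigs_per_day",
                    "wood_crop_kg_day", "coal_kg_day", "lpg_kg_day",
                )
            },
        )
        for name, params in pop.regions.items()
    }
    return replace(pop, regions=regions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
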