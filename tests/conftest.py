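import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from synthtl.ode_library import get_system
from synthtl.synth_generator import (DiversityConfig, NoiseConfig, TimeGrid,
                                     generate_dataset)

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def sir():
    return get_system("sir")


@pytest.fixture(scope="session")
def lv():
    return get_system("lv")


@pytest.fixture(scope="session")
def sar():
    return get_system("sar")


@pytest.fixture(scope="session")
def sir_grid():
    return TimeGrid.regular(0.0, 90.0, 91)


@pytest.fixture(scope="session")
def small_sir_dataset(sir, sir_grid):
    """20 noise-free SIR waves with medium IC/KP diversity."""
    div = DiversityConfig.from_classes(sir, "M", "M")
    return generate_dataset(sir, div, NoiseConfig(kind="none"), 20, sir_grid,
                            seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
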