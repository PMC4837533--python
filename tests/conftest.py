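import numpy as np
import pytest

from massgain.genetic_model import marker_table_for, scenario_grid


@pytest.fixture(scope="session")
def scenarios():
    """The 16-scenario (H, P) grid at V_P = 200."""
    return scenario_grid()


@pytest.fixture(scope="session")
def scenario1(scenarios):
    return scenarios[0]  # H=0.2, P=0.2


@pytest.fixture(scope="session")
def scenario2(scenarios):
    return scenarios[1]  # H=0.2, P=0.5


@pytest.fixture(scope="session")
def scenario6(scenarios):
    return scenarios[5]  # H=0.5, P=0.5


@pytest.fixture(scope="session")
def scenario16(scenarios):
    return scenarios[15]  # H=1, P=1 (no environmental or background noise)


@pytest.fixture(scope="session")
def table16_d0(scenario16):
    """Three-genotype, no dominance, a3 = 20: the fully deterministic case."""
    return marker_table_for(scenario16, "three_genotype", "none")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
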