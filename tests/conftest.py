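import numpy as np
import pytest
from hypothesis import settings

from psmforest import SimulationConfig, make_table1_schema, simulate_cohort

# derandomized property tests: identical examples in every environment
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schema():
    return make_table1_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient heterogeneous cohort shared by fast unit tests."""
    cohort, truth = simulate_cohort(SimulationConfig(n_patients=120, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """400-patient cohort for sweep-level tests."""
    cohort, truth = simulate_cohort(SimulationConfig(n_patients=400, seed=23))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
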