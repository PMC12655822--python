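import numpy as np
import pytest

from serscyto import (
    AxisSpec,
    PopulationConfig,
    default_reference_library,
    simulate_cell_population,
)


@pytest.fixture(scope="session")
def axis():
    return AxisSpec()


@pytest.fixture(scope="session")
def library(axis):
    return default_reference_library(axis)


@pytest.fixture(scope="session")
def population_frame():
    """Default three-line population, 300 cells per line, fixed seed."""
    return simulate_cell_population(PopulationConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
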