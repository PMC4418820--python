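import pytest

from eprkit import (
    DOXIL_PK,
    DOXORUBICIN_PK,
    ModelState,
    SimulationGrid,
    derive_rate_constants,
)


@pytest.fixture(scope="session")
def doxil_rates():
    return derive_rate_constants(DOXIL_PK)


@pytest.fixture(scope="session")
def dox_rates():
    return derive_rate_constants(DOXORUBICIN_PK)


@pytest.fixture
def doxil_init():
    return ModelState(t=0.0, N_bl=DOXIL_PK.initial_amount)


@pytest.fixture
def dox_init():
    return ModelState(t=0.0, N_bl=DOXORUBICIN_PK.initial_amount)


@pytest.fixture
def doxil_grid():
    return SimulationGrid(t_end=240.0)


@pytest.fixture
def dox_grid():
    return SimulationGrid(t_end=48.0)
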