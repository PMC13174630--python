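import numpy as np
import pytest

from sansr import basal_params, initial_state, simulate_cell


@pytest.fixture(scope="session")
def basal():
    return basal_params()


@pytest.fixture(scope="session")
def dormant(basal):
    """Dormant-zone parameter fixture (low SR pumping, reduced I_CaL)."""
    return basal.copy(g_CaL=0.37, P_up=1.0)


@pytest.fixture(scope="session")
def init_state():
    return initial_state()


@pytest.fixture(scope="session")
def basal_run(basal):
    """One 20 s basal simulation shared across tests (read-only)."""
    return simulate_cell(basal, duration=20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
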