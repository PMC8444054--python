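import datetime as dt

import pytest

import regionsim as rs
from regionsim.scenarios import ForecastWindow, enumerate_combinations, sweep_catchment

STATE_SEED = 1


@pytest.fixture(scope="session")
def grid20():
    """The standard 20-model-year grid from 1 Jan 2011 at dt = 1/8 week."""
    return rs.build_time_grid(dt.date(2011, 1, 1), 20, 8)


@pytest.fixture(scope="session")
def window():
    return ForecastWindow(dt.date(2021, 1, 1), dt.date(2031, 1, 1))


@pytest.fixture(scope="session")
def catalogue():
    return rs.default_catalogue()


@pytest.fixture(scope="session")
def synthetic_state():
    """The ten-catchment synthetic state (deterministic seed)."""
    return rs.generate_state(STATE_SEED, 10)


@pytest.fixture(scope="session")
def remote_catchment(synthetic_state):
    return next(p for p in synthetic_state if "remote" in p.name)


@pytest.fixture(scope="session")
def metro_catchment(synthetic_state):
    return next(p for p in synthetic_state if "metro" in p.name)


@pytest.fixture(scope="session")
def sweeps_k4(synthetic_state, grid20, window, catalogue):
    """Per-catchment sweeps of all 715 four-intervention subsets."""
    sets = enumerate_combinations(catalogue, 4)
    return [sweep_catchment(p, sets, grid20, window, catalogue) for p in synthetic_state]


@pytest.fixture(scope="session")
def sweeps_k5(synthetic_state, grid20, window, catalogue):
    sets = enumerate_combinations(catalogue, 5)
    return [sweep_catchment(p, sets, grid20, window, catalogue) for p in synthetic_state]
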