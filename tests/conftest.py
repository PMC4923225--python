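import pytest

from lungno.cycle import BreathingPattern
from lungno.lumen import TransportModel, simulate_cycle
from lungno.morphometry import WallLayerSpec, apply_alterations, load_morphometry


@pytest.fixture(scope="session")
def table():
    return load_morphometry()


@pytest.fixture(scope="session")
def walls():
    return WallLayerSpec()


@pytest.fixture(scope="session")
def healthy_rest(table):
    return apply_alterations(table)


@pytest.fixture(scope="session")
def classical_pattern():
    return BreathingPattern.classical()


@pytest.fixture(scope="session")
def healthy_model_fixture(healthy_rest, classical_pattern):
    return TransportModel(rest=healthy_rest, pattern=classical_pattern)


@pytest.fixture(scope="session")
def healthy_cycle(healthy_model_fixture):
    """One classical FE_NO maneuver of healthy lungs (protocol: NO-free start)."""
    return simulate_cycle(healthy_model_fixture)


@pytest.fixture(scope="session")
def healthy_two_cycles(healthy_model_fixture):
    """Two chained cycles: the second is representative of ongoing breathing."""
    return simulate_cycle(healthy_model_fixture, n_cycles=2)
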