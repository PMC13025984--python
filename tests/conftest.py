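import pytest

from algoreg import membrane, tilt, universe, workbench
from algoreg.estimators import LZ76Estimator


@pytest.fixture(scope="session")
def default_table():
    """The default desk-scale universe (L=22, step cap 256)."""
    return universe.default_universe()


@pytest.fixture(scope="session")
def string_table():
    """The larger string universe whose literals cover pair encodings."""
    return tilt.default_string_universe()


@pytest.fixture(scope="session")
def pair_universe():
    return tilt.build_pair_universe(max_joint_bits=24, horizon=8)


@pytest.fixture(scope="session")
def readout_suite(pair_universe):
    return tilt.default_readout_suite(pair_universe, n=10)


@pytest.fixture(scope="session")
def thermostat_episodes():
    """20 paired ON/OFF readouts under the default study conditions."""
    return workbench.thermostat_fixture(seed=11, n_episodes=20)


@pytest.fixture(scope="session")
def membrane_fixture():
    return membrane.blinker_noise_fixture(seed=7)


@pytest.fixture(scope="session")
def lz76_bin():
    return LZ76Estimator(alphabet_size=2)


@pytest.fixture(scope="session")
def lz76_oct():
    return LZ76Estimator(alphabet_size=8)
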