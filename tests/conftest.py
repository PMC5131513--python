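import pytest

from cryptodelim import fixtures
from cryptodelim.synthetic_data import milicia_like_scenario

#: canonical demonstration seed used throughout the suite
SCENARIO_SEED = 42


@pytest.fixture(scope="session")
def scenario():
    """The full synthetic study (435 individuals, 6 clusters, 3 species pools)."""
    return milicia_like_scenario(SCENARIO_SEED)


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_crosstab_fixture()


@pytest.fixture(scope="session")
def table3():
    return fixtures.load_distance_fixtures()
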