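import pytest

import rayleighsim as rs


@pytest.fixture(scope="session")
def grid():
    return rs.DEFAULT_GRID


@pytest.fixture(scope="session")
def pre(grid):
    return rs.default_prereceptoral(grid)


@pytest.fixture(scope="session")
def normal_set(grid, pre):
    return rs.build_normal_fundamentals(grid, pre=pre)


@pytest.fixture(scope="session")
def penn():
    return rs.make_instrument("penn")


@pytest.fixture(scope="session")
def oculus():
    return rs.make_instrument("oculus")


@pytest.fixture(scope="session")
def nagel():
    return rs.make_instrument("nagel")


@pytest.fixture(scope="session")
def normal_observer(normal_set):
    return rs.make_normal_observer(normal_set)
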