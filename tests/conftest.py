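import pytest

import orbiteq as oq


@pytest.fixture(scope="session")
def catalog2():
    return oq.enumerate_graphlets(2)


@pytest.fixture(scope="session")
def catalog3():
    return oq.enumerate_graphlets(3)


@pytest.fixture(scope="session")
def catalog4():
    return oq.enumerate_graphlets(4)


@pytest.fixture(scope="session")
def catalog5():
    return oq.enumerate_graphlets(5)


@pytest.fixture(scope="session")
def catalog6():
    return oq.enumerate_graphlets(6)


@pytest.fixture(scope="session")
def system3(catalog3, catalog2):
    return oq.generate_system(catalog3, catalog2)


@pytest.fixture(scope="session")
def system4(catalog4, catalog3):
    return oq.generate_system(catalog4, catalog3)


@pytest.fixture(scope="session")
def system5(catalog5, catalog4):
    return oq.generate_system(catalog5, catalog4)


@pytest.fixture(scope="session")
def system6(catalog6, catalog5):
    return oq.generate_system(catalog6, catalog5)


# --- small structural building blocks -----------------------------------

#: the order-5 graphlet with a central vertex joined to all others and two
#: disjoint edges among them (edge set printed in the source material)
G18_EDGES = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 4), (2, 3)]


@pytest.fixture
def graphlet18():
    return oq.make_graphlet(5, G18_EDGES)


@pytest.fixture
def triangle():
    return oq.make_graphlet(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return oq.make_graphlet(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def triangle_rep(catalog3):
    # the single-orbit triangle representative, via the catalog
    return list(catalog3.orbit_representatives())[2].representative


@pytest.fixture(scope="session")
def path_end_rep(catalog3):
    return list(catalog3.orbit_representatives())[0].representative


@pytest.fixture(scope="session")
def path_mid_rep(catalog3):
    return list(catalog3.orbit_representatives())[1].representative
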