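import numpy as np
import pytest

from ionhydrate import forcefield as ff


@pytest.fixture(scope="session")
def water_sp():
    return ff.water()


@pytest.fixture(scope="session")
def sulfite_sp():
    return ff.sulfite()


@pytest.fixture(scope="session")
def chlorate_sp():
    return ff.chlorate()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cluster(species_list, rng, spread=3.0):
    """Well-separated random cluster (no site overlaps)."""
    from ionhydrate.optimize import random_initial_cluster

    return random_initial_cluster(tuple(species_list), rng, min_separation=2.4,
                                  radius=spread * len(species_list) ** (1 / 3))


@pytest.fixture(scope="session")
def two_water_fixture(water_sp):
    """Fixed, documented two-water configuration used by energy oracles."""
    T = np.array([[0.0, 0.0, 0.0], [2.85, 0.4, -0.3]])
    P = np.array([[0.1, -0.2, 0.3], [1.1, 0.4, -0.5]])
    return ff.ClusterConfig((water_sp, water_sp), T, P)
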