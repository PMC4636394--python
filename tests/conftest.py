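import numpy as np
import pytest

import ryrcn as R
from ryrcn.mean_field import CNRates

NOMINAL = CNRates(beta=0.115, delta=0.5)


@pytest.fixture(scope="session")
def rect7x7():
    return R.generate_rect_lattice(7, 7)


@pytest.fixture(scope="session")
def adj7x7(rect7x7):
    return R.build_adjacency(rect7x7)


@pytest.fixture(scope="session")
def eig7x7(adj7x7):
    return R.eigendecompose(adj7x7)


@pytest.fixture(scope="session")
def nominal_rates():
    return NOMINAL


@pytest.fixture(scope="session")
def domino():
    """1x2 cluster: the smallest coupled system, fully solvable by hand."""
    return R.generate_rect_lattice(1, 2)


@pytest.fixture(scope="session")
def adj_domino(domino):
    return R.build_adjacency(domino)


@pytest.fixture(scope="session")
def small_cluster_family():
    """Connected clusters with n = 2..8 spanning paths, blocks and blobs."""
    return {
        "domino": R.generate_rect_lattice(1, 2),
        "path3": R.generate_rect_lattice(1, 3),
        "square4": R.generate_rect_lattice(2, 2),
        "L5": R.LatticeCluster(((0, 0), (1, 0), (2, 0), (2, 1), (2, 2)), label="L5"),
        "rect6": R.generate_rect_lattice(2, 3),
        "rand8": R.generate_random_cluster(8, 3),
    }
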