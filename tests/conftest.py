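import numpy as np
import pytest
from hypothesis import settings

from braingraph import BinaryGraph

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


def graph_from_edges(n, edges, labels=None):
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return BinaryGraph(A, labels or [])


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4():
    return graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def star5():
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def two_triangles():
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def random_connected_graph(n, rng, p=0.5):
    """A connected Erdos-Renyi-style graph, resampled until connected."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    while True:
        upper = rng.random((n, n)) < p
        A = np.triu(upper, k=1).astype(int)
        A = A + A.T
        if A.sum() and connected_components(csr_matrix(A), directed=False)[0] == 1:
            return A


def ring_lattice(n, k):
    """Each node connected to its k nearest neighbours on a ring (k even)."""
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            A[i, j] = A[j, i] = 1
    return A
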