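"""Global and nodal topology measures for binary undirected graphs.

Measures follow the standard binary-graph definitions used throughout the
brain-connectivity literature: clustering and transitivity (segregation),
characteristic path length and global/local efficiency (integration),
betweenness centrality (hubness), degree assortativity (resilience) and
modularity of the best partition found by repeated community optimization.

Everything operates on dense numpy adjacency matrices so the measures stay
cheap inside permutation loops; graphs here have at most a few hundred
nodes.  On fragmented graphs, path length is computed on the largest
component only and a ``fragmented`` flag is set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .graph_construction import BinaryGraph

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "Partition",
    "degrees",
    "clustering_coefficients",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "transitivity",
    "assortativity",
    "largest_component_size",
    "modularity_best_partition",
    "global_metrics",
    "nodal_metrics",
    "global_metric_function",
    "nodal_metric_function",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]


def _adj(G) -> np.ndarray:
    A = G.A if isinstance(G, BinaryGraph) else np.asarray(G)
    return A.astype(float)


def degrees(G) -> np.ndarray:
    return _adj(G).sum(axis=0)


def clustering_coefficients(G) -> tuple[np.ndarray, float]:
    """Per-node clustering and the network mean C.

    Node value = 2 * (edges among neighbors) / (k(k-1)); degree-0/1 nodes
    score 0 and are included in the mean.
    """
    A = _adj(G)
    k = A.sum(axis=0)
    closed = np.einsum("ij,jk,ki->i", A, A, A)  # 2x triangles per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, closed / denom, 0.0)
    return c, float(c.mean())


def transitivity(G) -> float:
    """3 * triangles / connected triples; 0 when no triple exists."""
    A = _adj(G)
    k = A.sum(axis=0)
    closed = np.trace(A @ A @ A)  # 6x triangles
    triples = (k * (k - 1)).sum()  # 2x connected triples
    if triples == 0:
        return 0.0
    return float(closed / triples)


def _distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(A), method="D", directed=False,
                         unweighted=True)


def characteristic_path_length(G) -> tuple[float, bool]:
    """Mean shortest-path length over pairs, and a fragmentation flag.

    On a fragmented graph the mean is restricted to pairs inside the largest
    connected component and the flag is True.
    """
    A = _adj(G)
    n = A.shape[0]
    if n < 2:
        return 0.0, False
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    if n_comp == 1:
        D = _distances(A)
        return float(D[np.triu_indices(n, k=1)].mean()), False
    comp = np.argmax(np.bincount(labels))
    idx = np.flatnonzero(labels == comp)
    if len(idx) < 2:
        return 0.0, True
    D = _distances(A[np.ix_(idx, idx)])
    return float(D[np.triu_indices(len(idx), k=1)].mean()), True


def global_efficiency(G) -> float:
    """Mean inverse shortest-path length over all pairs (0 for disconnected)."""
    A = _adj(G)
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = _distances(A)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(G) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and the network mean.

    Node value = global efficiency of the subgraph induced by the node's
    neighbors; degree-0/1 nodes score 0.
    """
    A = _adj(G)
    n = A.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if len(nbrs) < 2:
            continue
        eloc[i] = global_efficiency(A[np.ix_(nbrs, nbrs)])
    return eloc, float(eloc.mean())


def betweenness_centrality(G, normalized: bool = True) -> np.ndarray:
    """Exact shortest-path betweenness (Brandes accumulation via networkx).

    Normalized by (N-1)(N-2)/2 when ``normalized`` — a pure rescaling that
    does not affect mean + k*SD hub selection.
    """
    A = _adj(G)
    g = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return np.array([bc[i] for i in range(A.shape[0])])


def nodal_path_length(G) -> tuple[np.ndarray, bool]:
    """Per-node mean shortest distance to all other reachable nodes.

    On fragmented graphs, unreachable pairs are excluded per node and the
    fragmentation flag is True; isolated nodes score inf.
    """
    A = _adj(G)
    n = A.shape[0]
    D = _distances(A)
    np.fill_diagonal(D, np.nan)
    finite = np.isfinite(D)
    fragmented = not finite[~np.isnan(D)].all() if n > 1 else False
    out = np.full(n, np.inf)
    for i in range(n):
        reach = D[i][finite[i]]
        if len(reach):
            out[i] = reach.mean()
    return out, fragmented


def assortativity(G) -> float:
    """Pearson correlation of degrees at the two ends of each edge.

    NaN (with a warning) for degree-regular graphs where the edge-end degree
    variance vanishes.
    """
    A = _adj(G)
    k = A.sum(axis=0)
    ii, jj = np.nonzero(np.triu(A, k=1))
    if len(ii) == 0:
        warnings.warn("assortativity undefined: no edges", stacklevel=2)
        return float("nan")
    # each undirected edge contributes both orientations
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    if x.std() == 0 or y.std() == 0:
        warnings.warn(
            "assortativity undefined: zero degree variance over edge ends",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def largest_component_size(G) -> int:
    A = _adj(G)
    _, labels = connected_components(csr_matrix(A), directed=False)
    return int(np.bincount(labels).max())


@dataclass
class Partition:
    """Node-to-module assignment with its modularity Q."""

    membership: np.ndarray
    q: float

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.membership))


def _modularity_q(A: np.ndarray, membership: np.ndarray) -> float:
    k = A.sum(axis=0)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    same = membership[:, None] == membership[None, :]
    return float(((A - np.outer(k, k) / two_m) * same).sum() / two_m)


def modularity_best_partition(
    G,
    iterations: int = 100,
    method: str = "louvain",
    seed: int | None = None,
) -> Partition:
    """Best-of-``iterations`` community partition by modularity Q.

    The optimizer (multi-level Louvain by default, greedy agglomerative as the
    alternative) is restarted ``iterations`` times with distinct seeded random
    orders and the partition with the highest Q is returned, to characterize
    the degeneracy of near-optimal modular structure.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    A = _adj(G)
    if A.sum() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    g = nx.from_numpy_array(A)
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best = None
    if method == "greedy":
        # deterministic agglomeration; a single run suffices
        communities = nx.community.greedy_modularity_communities(g)
        best = communities
        best_q = None
    elif method == "louvain":
        for _ in range(iterations):
            sub = int(rng.integers(0, 2**31 - 1))
            communities = nx.community.louvain_communities(g, seed=sub)
            membership = _communities_to_membership(communities, A.shape[0])
            q = _modularity_q(A, membership)
            if q > best_q:
                best_q, best = q, communities
    else:
        raise ValueError(f"unknown modularity method: {method!r}")
    membership = _communities_to_membership(best, A.shape[0])
    q = _modularity_q(A, membership)
    return Partition(membership, q)


def _communities_to_membership(communities, n: int) -> np.ndarray:
    membership = np.empty(n, dtype=int)
    for m, com in enumerate(communities):
        for node in com:
            membership[node] = m
    return membership


@dataclass
class GlobalMetrics:
    """Whole-network summary at one density."""

    clustering: float
    path_length: float
    global_efficiency: float
    local_efficiency: float
    transitivity: float
    assortativity: float
    modularity: float
    largest_component: int
    fragmented: bool


@dataclass
class NodalMetrics:
    """Per-region measures at one density."""

    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    local_efficiency: np.ndarray
    path_length: np.ndarray
    region_labels: list = field(default_factory=list)
    fragmented: bool = False


def global_metrics(
    G, *, modularity_iterations: int = 20, seed: int | None = None
) -> GlobalMetrics:
    """All global measures of one graph in a single call."""
    _, C = clustering_coefficients(G)
    L, fragmented = characteristic_path_length(G)
    _, eloc = local_efficiency(G)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_assort = assortativity(G)
    return GlobalMetrics(
        clustering=C,
        path_length=L,
        global_efficiency=global_efficiency(G),
        local_efficiency=eloc,
        transitivity=transitivity(G),
        assortativity=r_assort,
        modularity=modularity_best_partition(
            G, iterations=modularity_iterations, seed=seed
        ).q,
        largest_component=largest_component_size(G),
        fragmented=fragmented,
    )


def nodal_metrics(G) -> NodalMetrics:
    """All nodal measures of one graph in a single call."""
    c, _ = clustering_coefficients(G)
    eloc, _ = local_efficiency(G)
    pl, fragmented = nodal_path_length(G)
    labels = list(G.region_labels) if isinstance(G, BinaryGraph) else []
    return NodalMetrics(
        degree=degrees(G),
        clustering=c,
        betweenness=betweenness_centrality(G),
        local_efficiency=eloc,
        path_length=pl,
        region_labels=labels,
        fragmented=fragmented,
    )


GLOBAL_METRIC_NAMES = (
    "clustering",
    "path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "assortativity",
    "modularity",
    "largest_component",
)

NODAL_METRIC_NAMES = (
    "degree",
    "clustering",
    "betweenness",
    "local_efficiency",
    "path_length",
)


def global_metric_function(name: str, *, seed: int | None = None):
    """Scalar metric evaluator by name, for permutation loops."""
    if name == "clustering":
        return lambda G: clustering_coefficients(G)[1]
    if name == "path_length":
        return lambda G: characteristic_path_length(G)[0]
    if name == "global_efficiency":
        return global_efficiency
    if name == "local_efficiency":
        return lambda G: local_efficiency(G)[1]
    if name == "transitivity":
        return transitivity
    if name == "assortativity":
        def _assort(G):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return assortativity(G)
        return _assort
    if name == "modularity":
        return lambda G: modularity_best_partition(
            G, iterations=10, seed=seed
        ).q
    if name == "largest_component":
        return lambda G: float(largest_component_size(G))
    raise ValueError(f"unknown global metric: {name!r}")


def nodal_metric_function(name: str):
    """Per-node metric evaluator by name, for permutation loops."""
    if name == "degree":
        return degrees
    if name == "clustering":
        return lambda G: clustering_coefficients(G)[0]
    if name == "betweenness":
        return betweenness_centrality
    if name == "local_efficiency":
        return lambda G: local_efficiency(G)[0]
    if name == "path_length":
        return lambda G: nodal_path_length(G)[0]
    raise ValueError(f"unknown nodal metric: {name!r}")
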