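"""Benchmark null networks and normalized small-world statistics.

Small-worldness is judged against matched random benchmarks: either
degree-preserving edge rewiring of the observed graph (topology mode) or
random correlation matrices matched to the off-diagonal moments of the
observed association matrix (covariance mode).  The small-world index is
sigma = (C/C_rand) / (L/L_rand), with C_rand and L_rand the ensemble means
over m null networks; sigma well above 1 marks a network that clusters far
more than random while keeping near-random path lengths.

Covariance-mode nulls matter for correlation networks, which are inherently
more clustered than degree-matched random graphs; the choice of null model
strongly affects small-world metrics at low densities (below ~0.2), so a
warning is emitted there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_construction import AssociationMatrix, BinaryGraph, threshold_at_density
from .graph_metrics import characteristic_path_length, clustering_coefficients

__all__ = [
    "NullEnsemble",
    "SmallWorldMetrics",
    "rewire_preserving_degree",
    "randomize_covariance",
    "topology_null_ensemble",
    "covariance_null_ensemble",
    "small_world",
    "DEFAULT_ENSEMBLE_SIZE",
]

DEFAULT_ENSEMBLE_SIZE = 20  # null networks per normalization


@dataclass
class NullEnsemble:
    """A set of benchmark null networks (or null association matrices)."""

    members: list
    mode: str  # "topology" | "covariance"

    @property
    def m(self) -> int:
        return len(self.members)


@dataclass
class SmallWorldMetrics:
    """Normalized clustering/path-length and the small-world index.

    gamma = C / C_rand, lam = L / L_rand, sigma = gamma / lam.
    """

    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float

    @property
    def gamma(self) -> float:
        return self.clustering / self.clustering_rand

    @property
    def lam(self) -> float:
        return self.path_length / self.path_length_rand

    @property
    def sigma(self) -> float:
        return self.gamma / self.lam


def _substreams(seed, n: int) -> list[int]:
    """Derive n independent per-member seeds from one master seed."""
    master = np.random.default_rng(seed)
    return [int(s) for s in master.integers(0, 2**31 - 1, size=n)]


def rewire_preserving_degree(
    G: BinaryGraph | np.ndarray,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> BinaryGraph:
    """Randomize edges by double-edge swaps, preserving every node's degree.

    Attempts ``swaps_per_edge * E`` swaps of edge pairs (a-b, c-d) -> (a-d,
    c-b), rejecting any swap that would create a self-loop or duplicate
    edge.  Degree sequence is preserved exactly.  If no valid swap exists
    (e.g. a star), the input is returned unchanged with a warning.
    """
    A = (G.A if isinstance(G, BinaryGraph) else np.asarray(G)).copy()
    labels = list(G.region_labels) if isinstance(G, BinaryGraph) else []
    ii, jj = np.nonzero(np.triu(A, k=1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    attempts = swaps_per_edge * n_edges
    successes = 0
    for _ in range(attempts):
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a-d, c-b)
        if a == d or c == b:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        successes += 1
    if successes == 0:
        warnings.warn(
            "no valid degree-preserving swap found; returning the input graph",
            stacklevel=2,
        )
    return BinaryGraph(A, labels)


def randomize_covariance(
    R: AssociationMatrix | np.ndarray, seed: int | None = None
) -> AssociationMatrix:
    """Random correlation matrix matched to R's off-diagonal moments.

    A random-factor construction: draw an N x k factor matrix F with i.i.d.
    Gaussian entries of mean mu and SD s, form the Gram matrix F F^T and
    normalize it to unit diagonal.  mu and s are solved so the Gram
    off-diagonals match R's off-diagonal mean and variance in expectation,
    and k is chosen so the expected pre-normalization diagonal is closest to
    1 (normalization then perturbs the moments least).  The output is
    symmetric and positive semi-definite by construction; R's specific
    correlation structure is destroyed.
    """
    Rm = R.R if isinstance(R, AssociationMatrix) else np.asarray(R, dtype=float)
    labels = list(R.region_labels) if isinstance(R, AssociationMatrix) else []
    n = Rm.shape[0]
    iu = np.triu_indices(n, k=1)
    e = float(Rm[iu].mean())
    v = float(Rm[iu].var())
    v = max(v, 1e-12)
    if e < 0:
        warnings.warn(
            "off-diagonal mean is negative; the factor construction matches "
            "mean 0 instead (closest achievable)",
            stacklevel=2,
        )
        e = 0.0
    # For entries F_ij ~ N(mu, s^2): E[(FF^T)_{ij}] = k mu^2 (i != j),
    # Var[(FF^T)_{ij}] = k (s^4 + 2 mu^2 s^2), E[(FF^T)_{ii}] = k (mu^2 + s^2).
    best = None
    for k in range(1, max(2 * n, 8) + 1):
        mu2 = e / k
        s2 = -mu2 + np.sqrt(mu2**2 + v / k)
        diag = k * (mu2 + s2)
        score = abs(diag - 1.0)
        if best is None or score < best[0]:
            best = (score, k, mu2, s2)
    _, k, mu2, s2 = best
    rng = np.random.default_rng(seed)
    F = rng.normal(np.sqrt(mu2), np.sqrt(s2), size=(n, k))
    C = F @ F.T
    d = np.sqrt(np.diag(C))
    d[d == 0] = 1.0
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 0.0)
    return AssociationMatrix(np.clip(C, -1, 1), "null", labels)


def topology_null_ensemble(
    G: BinaryGraph,
    m: int = DEFAULT_ENSEMBLE_SIZE,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> NullEnsemble:
    """m degree-preserving rewired copies of G, seeded per member."""
    seeds = _substreams(seed, m)
    members = [
        rewire_preserving_degree(G, swaps_per_edge=swaps_per_edge, seed=s)
        for s in seeds
    ]
    return NullEnsemble(members, "topology")


def covariance_null_ensemble(
    R: AssociationMatrix,
    m: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int | None = None,
) -> NullEnsemble:
    """m moment-matched random association matrices, seeded per member."""
    seeds = _substreams(seed, m)
    members = [randomize_covariance(R, seed=s) for s in seeds]
    return NullEnsemble(members, "covariance")


def small_world(
    G: BinaryGraph,
    null: NullEnsemble,
    density: float | None = None,
) -> SmallWorldMetrics:
    """Normalized small-world statistics of G against a null ensemble.

    Covariance-mode ensemble members are thresholded at ``density`` (must be
    given, and should equal G's density) before metric extraction; topology
    members are used as-is.  Fragmented null members contribute their
    largest-component path length.
    """
    if density is not None and density < 0.2:
        warnings.warn(
            "small-world metrics are sensitive to the null-model choice at "
            "densities below 0.2; interpret with care",
            stacklevel=2,
        )
    if null.mode == "covariance":
        if density is None:
            raise ValueError("covariance-mode ensembles require a density")
        graphs = [threshold_at_density(m, density) for m in null.members]
    else:
        graphs = null.members
    _, C = clustering_coefficients(G)
    L, _ = characteristic_path_length(G)
    c_rand = float(np.mean([clustering_coefficients(g)[1] for g in graphs]))
    l_rand = float(np.mean([characteristic_path_length(g)[0] for g in graphs]))
    if c_rand <= 0 or l_rand <= 0:
        raise ValueError("degenerate null ensemble (zero mean C or L)")
    return SmallWorldMetrics(C, L, c_rand, l_rand)
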