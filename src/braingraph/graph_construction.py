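"""Association matrices, density thresholding and the minimum connected density.

A group's network is built in two steps: correlate regional values across
subjects into an N x N association matrix R, then binarize R at a target
density D by keeping the E = round(D * N(N-1)/2) strongest (signed) pairwise
correlations as edges.  Density-based thresholding guarantees both groups'
graphs have the same number of nodes and edges, so topological differences
are not confounded by trivial differences in edge counts.

``find_dmin`` scans a density grid for the smallest density at which every
supplied network is a single connected component — the customary lower bound
of the analysis range, below which graphs fragment and metrics lose
comparability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .roi_extract import RegionalDataTable

__all__ = [
    "AssociationMatrix",
    "BinaryGraph",
    "DensityGrid",
    "association_matrix",
    "threshold_at_density",
    "find_dmin",
    "zscores_to_r",
    "is_fragmented",
    "max_edges",
    "edge_count_for_density",
]


@dataclass
class AssociationMatrix:
    """Symmetric N x N matrix of inter-regional correlations, zero diagonal."""

    R: np.ndarray
    method: str = "pearson"
    region_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 0.0)
        if np.nanmax(np.abs(R)) > 1 + 1e-9:
            raise ValueError("association entries must lie in [-1, 1]")
        self.R = np.clip(R, -1.0, 1.0)
        if not self.region_labels:
            self.region_labels = [f"roi-{i:03d}" for i in range(R.shape[0])]
        self.region_labels = [str(r) for r in self.region_labels]
        if len(self.region_labels) != R.shape[0]:
            raise ValueError("region_labels length does not match R")

    @property
    def n_regions(self) -> int:
        return self.R.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.region_labels,
                            columns=self.region_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, method: str = "pearson") -> "AssociationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), method, list(df.columns))


@dataclass
class BinaryGraph:
    """Binary undirected graph as an N x N adjacency matrix.

    ``density`` is the fraction of realized connections, E / (N(N-1)/2).
    """

    A: np.ndarray
    region_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("A must have zero diagonal")
        uniq = np.unique(A)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("A must be binary")
        self.A = A.astype(np.uint8)
        if not self.region_labels:
            self.region_labels = [f"roi-{i:03d}" for i in range(A.shape[0])]
        self.region_labels = [str(r) for r in self.region_labels]
        if len(self.region_labels) != A.shape[0]:
            raise ValueError("region_labels length does not match A")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    @property
    def density(self) -> float:
        return self.n_edges / max_edges(self.n_nodes)

    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=0).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.A)
        return nx.relabel_nodes(
            g, dict(enumerate(self.region_labels)), copy=True
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.A, index=self.region_labels,
                     columns=self.region_labels).to_csv(path)


@dataclass(frozen=True)
class DensityGrid:
    """Densities d_min, d_min+step, ... up to d_max (inclusive to fp tolerance)."""

    d_min: float
    d_max: float
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.d_min <= self.d_max <= 1):
            raise ValueError("require 0 < d_min <= d_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def densities(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return np.round(self.d_min + self.step * np.arange(n), 12)

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)


def max_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_count_for_density(density: float, n_nodes: int) -> int:
    """Edge count for a target density: round-half-away-from-zero of D*N(N-1)/2."""
    m = density * max_edges(n_nodes)
    return int(np.floor(m + 0.5))


def association_matrix(
    data: RegionalDataTable, method: str = "pearson"
) -> AssociationMatrix:
    """Correlate regional values across subjects into an association matrix.

    ``method="pearson"`` gives plain pairwise Pearson correlations;
    ``method="partial"`` gives pairwise correlations conditioned on all
    remaining regions, computed from the inverse of the full correlation
    matrix.  Partial correlations require more subjects than regions (the
    correlation matrix must be invertible) and are unstable for small
    samples.
    """
    X = data.values
    n_subj, n_reg = X.shape
    if n_reg < 3:
        raise ValueError("need at least 3 regions to build a network")
    sd = X.std(axis=0)
    dead = [l for l, s in zip(data.region_labels, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance region(s): {dead}")
    if method == "pearson":
        if n_subj < 3:
            raise ValueError("pearson correlation needs at least 3 subjects")
        R = np.corrcoef(X, rowvar=False)
    elif method == "partial":
        if n_subj <= n_reg:
            raise ValueError(
                f"partial correlation needs more subjects ({n_subj}) than "
                f"regions ({n_reg}); correlation matrix is singular"
            )
        if n_subj < 2 * n_reg:
            warnings.warn(
                "partial correlations are unreliable when the sample size is "
                "not well above the number of regions",
                stacklevel=2,
            )
        C = np.corrcoef(X, rowvar=False)
        P = np.linalg.inv(C)
        d = np.sqrt(np.diag(P))
        R = -P / np.outer(d, d)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    np.fill_diagonal(R, 0.0)
    return AssociationMatrix(np.clip(R, -1, 1), method, data.region_labels)


def _ranked_pairs(R: np.ndarray):
    """Upper-triangle pairs ordered by descending signed weight.

    Ties are broken by ascending (i, j) lexicographic node order so the edge
    set at any density is deterministic across runs and platforms.
    """
    n = R.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = R[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_at_density(
    R: AssociationMatrix | np.ndarray, density: float,
    region_labels: Sequence[str] | None = None,
) -> BinaryGraph:
    """Binarize an association matrix at a target density.

    The E = round(D * N(N-1)/2) node pairs with the largest *signed*
    correlation become edges; negative correlations therefore only enter at
    very high densities.  Ties at the cutoff weight are resolved by ascending
    lexicographic node order.
    """
    if isinstance(R, AssociationMatrix):
        labels = list(R.region_labels)
        Rm = R.R
    else:
        Rm = np.asarray(R, dtype=float)
        labels = list(region_labels) if region_labels is not None else []
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n = Rm.shape[0]
    n_edges = edge_count_for_density(density, n)
    if n_edges == 0:
        raise ValueError(
            f"density {density} yields zero edges for {n} nodes"
        )
    ii, jj = _ranked_pairs(Rm)
    A = np.zeros((n, n), dtype=np.uint8)
    A[ii[:n_edges], jj[:n_edges]] = 1
    A |= A.T
    return BinaryGraph(A, labels)


def is_fragmented(G: BinaryGraph | np.ndarray) -> tuple[bool, list[int]]:
    """Whether the graph has >1 connected component, plus component sizes.

    Component sizes are returned sorted in descending order.
    """
    A = G.A if isinstance(G, BinaryGraph) else np.asarray(G)
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    sizes = sorted(np.bincount(labels).tolist(), reverse=True)
    return n_comp > 1, sizes


def find_dmin(
    matrices: AssociationMatrix | Iterable[AssociationMatrix],
    grid: DensityGrid,
) -> float:
    """Smallest grid density at which every network is fully connected.

    Scans the grid in ascending order, thresholds every association matrix
    and returns the first density where no thresholded graph is fragmented.
    """
    if isinstance(matrices, AssociationMatrix):
        matrices = [matrices]
    mats = list(matrices)
    if not mats:
        raise ValueError("no association matrices given")
    ranked = [_ranked_pairs(m.R) for m in mats]
    for density in grid:
        ok = True
        for m, (ii, jj) in zip(mats, ranked):
            n = m.n_regions
            n_edges = edge_count_for_density(density, n)
            if n_edges == 0:
                ok = False
                break
            A = np.zeros((n, n), dtype=np.uint8)
            A[ii[:n_edges], jj[:n_edges]] = 1
            A |= A.T
            if connected_components(csr_matrix(A), directed=False)[0] > 1:
                ok = False
                break
        if ok:
            return float(density)
    raise ValueError(
        f"no density up to {grid.d_max} yields fully connected networks; "
        "extend the grid upward"
    )


def zscores_to_r(
    Z: np.ndarray, region_labels: Sequence[str] | None = None
) -> list[AssociationMatrix]:
    """Back-convert per-subject Fisher z matrices to correlation matrices.

    Accepts a subjects × N × N array of Fisher z-scores; returns one
    association matrix per subject with r = tanh(z), symmetry enforced by
    averaging with the transpose and the diagonal zeroed.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 2:
        Z = Z[None]
    if Z.ndim != 3 or Z.shape[1] != Z.shape[2]:
        raise ValueError("Z must be a subjects x N x N array")
    out = []
    for s in range(Z.shape[0]):
        zs = Z[s]
        if not np.isfinite(zs).all():
            raise ValueError(f"non-finite z-scores for subject index {s}")
        r = np.tanh((zs + zs.T) / 2.0)
        np.fill_diagonal(r, 0.0)
        out.append(AssociationMatrix(r, "pearson", region_labels or []))
    return out
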