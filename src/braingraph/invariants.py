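"""Distance-based topological indices of connected undirected simple graphs.

For an edge ``e = rs`` let ``alpha_r`` and ``alpha_s`` count the vertices
strictly closer (in hop distance) to ``r`` and to ``s`` respectively;
equidistant vertices belong to neither side. The six indices computed here
are edge/pair sums over these quantities:

===============================  =====================================================
Szeged                 ``Sz``    sum over edges of ``alpha_r * alpha_s``
Graovac-Ghorbani       ``ABC``   sum of ``sqrt((alpha_r + alpha_s - 2) / (alpha_r * alpha_s))``
Padmakar-Ivan          ``PI``    sum of ``alpha_r + alpha_s``
Mostar                 ``MO``    sum of ``|alpha_r - alpha_s|``
normalized G-G         ``NGG``   sum of ``1 / sqrt(alpha_r * alpha_s)``
Wiener                 ``W``     sum of hop distances over unordered vertex pairs
===============================  =====================================================

A graph with ``alpha_r = alpha_s`` on every edge is *distance-balanced*,
equivalently ``MO = 0``. All indices require a connected graph; callers with
possibly-disconnected graphs should first take the largest component.

The heavy lifting is vectorized: one BFS all-pairs distance matrix
(scipy.sparse.csgraph) shared by all six indices, and chunked numpy
comparisons for the per-edge partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "DistanceMatrix",
    "EdgePartition",
    "IndexVector",
    "SmallWorldSummary",
    "all_pairs_distances",
    "edge_partition",
    "szeged",
    "graovac_ghorbani",
    "pi_index",
    "mostar",
    "ngg",
    "wiener",
    "compute_index_vector",
    "is_distance_balanced",
    "small_world_summary",
    "stats_from_adjacency",
    "largest_component_adjacency",
]

# edges are chunked so the (chunk x v) comparison buffers stay small
_CHUNK = 4096


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs hop distances of a connected graph.

    ``nodes[i]`` is the graph label of matrix row/column ``i``.
    """

    dist: np.ndarray
    nodes: tuple

    def __post_init__(self):
        object.__setattr__(self, "_pos", {n: i for i, n in enumerate(self.nodes)})

    def __getitem__(self, pair):
        r, s = pair
        return int(self.dist[self._pos[r], self._pos[s]])


@dataclass(frozen=True)
class EdgePartition:
    """Strictly-closer vertex counts for one edge ``rs``."""

    alpha_r: int
    alpha_s: int
    tie_count: int


@dataclass(frozen=True)
class IndexVector:
    """The six distance-based indices of one graph, in a fixed field order."""

    sz: float
    abc: float
    pi: float
    mo: float
    ngg: float
    w: float

    NAMES = ("Sz", "ABC", "PI", "MO", "NGG", "W")

    def to_array(self) -> np.ndarray:
        return np.array([self.sz, self.abc, self.pi, self.mo, self.ngg, self.w])

    @classmethod
    def from_array(cls, arr) -> "IndexVector":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class SmallWorldSummary:
    """Mean local clustering coefficient and average path length of a graph."""

    c_cc: float
    l_apl: float
    v: int
    mean_degree: float


def _to_arrays(g: nx.Graph):
    """Adjacency (bool) and node order of a graph; validates simplicity."""
    if g.number_of_nodes() < 2:
        raise ValueError("indices require a graph with at least 2 vertices")
    if any(g.has_edge(n, n) for n in g):
        raise ValueError("graph must be simple (self-loop found)")
    nodes = list(g.nodes())
    A = nx.to_numpy_array(g, nodelist=nodes, dtype=bool, weight=None)
    return A, nodes


def _distances(A: np.ndarray) -> np.ndarray:
    S = csr_matrix(A)
    ncomp, _ = connected_components(S, directed=False)
    if ncomp > 1:
        raise ValueError(
            "graph is disconnected; take the largest component before "
            "computing distance-based indices"
        )
    return shortest_path(S, method="D", unweighted=True)


def _partitions(A: np.ndarray, D: np.ndarray):
    """Per-edge (alpha_r, alpha_s) arrays for all edges of A (upper triangle)."""
    iu, ju = np.nonzero(np.triu(A, 1))
    ar = np.empty(len(iu), dtype=np.int64)
    as_ = np.empty(len(iu), dtype=np.int64)
    D16 = D.astype(np.int16)  # hop counts are tiny; halves memory traffic
    for lo in range(0, len(iu), _CHUNK):
        hi = lo + _CHUNK
        diff = D16[iu[lo:hi]] - D16[ju[lo:hi]]
        ar[lo:hi] = (diff < 0).sum(axis=1)
        as_[lo:hi] = (diff > 0).sum(axis=1)
    return iu, ju, ar, as_


def _clustering_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Per-vertex local clustering coefficients (0 for degree < 2)."""
    Af = A.astype(np.float32)
    tri = ((Af @ Af) * Af).sum(axis=1) / 2.0  # diag(A^3)/2 via BLAS
    deg = A.sum(axis=1)
    possible = deg * (deg - 1) / 2.0
    return np.divide(tri, possible, out=np.zeros(A.shape[0]), where=possible > 0)


def largest_component_adjacency(A: np.ndarray) -> np.ndarray:
    """Adjacency restricted to the largest connected component (ties: the
    component containing the smallest vertex index)."""
    ncomp, labels = connected_components(csr_matrix(A), directed=False)
    if ncomp == 1:
        return A
    counts = np.bincount(labels)
    # stable tie-break: among max-size components, np.argmax picks the one
    # whose label appears first, i.e. the one containing the smallest vertex
    keep = labels == np.argmax(counts)
    return A[np.ix_(keep, keep)]


def stats_from_adjacency(A: np.ndarray) -> dict:
    """All six indices plus C_cc and L_apl of a connected adjacency matrix.

    Array-level fast path shared by the ensemble and pipeline code; one BFS
    distance matrix and one partition pass feed every statistic. Keys:
    Sz, ABC, PI, MO, NGG, W, C_cc, L_apl.
    """
    D = _distances(A)
    _, _, ar, as_ = _partitions(A, D)
    prod = ar * as_
    v = A.shape[0]
    cc = _clustering_from_adjacency(A)
    return {
        "Sz": float(prod.sum()),
        "ABC": float(np.sqrt((ar + as_ - 2) / prod).sum()),
        "PI": float((ar + as_).sum()),
        "MO": float(np.abs(ar - as_).sum()),
        "NGG": float((1.0 / np.sqrt(prod)).sum()),
        "W": float(D.sum() / 2.0),
        "C_cc": float(cc.mean()),
        "L_apl": float(D.sum() / (v * (v - 1))),
    }


def all_pairs_distances(g: nx.Graph) -> DistanceMatrix:
    """BFS hop distances between all vertex pairs of a connected graph."""
    A, nodes = _to_arrays(g)
    return DistanceMatrix(dist=_distances(A), nodes=tuple(nodes))


def edge_partition(g: nx.Graph, e, dm: DistanceMatrix | None = None) -> EdgePartition:
    """Partition counts ``(alpha_r, alpha_s, ties)`` for edge ``e = (r, s)``.

    Equidistant vertices are counted only in ``tie_count``; each endpoint is
    closer to itself, so both alphas are >= 1 and the three counts sum to v.
    """
    r, s = e
    if not g.has_edge(r, s):
        raise ValueError(f"{e!r} is not an edge of the graph")
    if dm is None:
        dm = all_pairs_distances(g)
    pos = {n: i for i, n in enumerate(dm.nodes)}
    dr = dm.dist[pos[r]]
    ds = dm.dist[pos[s]]
    alpha_r = int((dr < ds).sum())
    alpha_s = int((ds < dr).sum())
    return EdgePartition(alpha_r, alpha_s, len(dm.nodes) - alpha_r - alpha_s)


def _index_values(A: np.ndarray) -> IndexVector:
    D = _distances(A)
    _, _, ar, as_ = _partitions(A, D)
    prod = ar * as_
    sz = int(prod.sum())
    pi = int((ar + as_).sum())
    mo = int(np.abs(ar - as_).sum())
    abc = float(np.sqrt((ar + as_ - 2) / prod).sum())
    ngg_v = float((1.0 / np.sqrt(prod)).sum())
    w = int(round(D.sum() / 2))
    return IndexVector(sz=sz, abc=abc, pi=pi, mo=mo, ngg=ngg_v, w=w)


def compute_index_vector(g: nx.Graph) -> IndexVector:
    """All six indices from one shared distance matrix and partition pass."""
    A, _ = _to_arrays(g)
    return _index_values(A)


def szeged(g: nx.Graph) -> int:
    """Szeged index ``sum_e alpha_r * alpha_s``."""
    return int(compute_index_vector(g).sz)


def graovac_ghorbani(g: nx.Graph) -> float:
    """Graovac-Ghorbani (ABC) index ``sum_e sqrt((alpha_r+alpha_s-2)/(alpha_r*alpha_s))``."""
    return compute_index_vector(g).abc


def pi_index(g: nx.Graph) -> int:
    """Padmakar-Ivan index ``sum_e (alpha_r + alpha_s)``."""
    return int(compute_index_vector(g).pi)


def mostar(g: nx.Graph) -> int:
    """Mostar index ``sum_e |alpha_r - alpha_s|``; 0 iff distance-balanced."""
    return int(compute_index_vector(g).mo)


def ngg(g: nx.Graph) -> float:
    """Normalized Graovac-Ghorbani index ``sum_e 1/sqrt(alpha_r*alpha_s)``."""
    return compute_index_vector(g).ngg


def wiener(g: nx.Graph) -> int:
    """Wiener index: sum of hop distances over unordered vertex pairs."""
    A, _ = _to_arrays(g)
    return int(round(_distances(A).sum() / 2))


def is_distance_balanced(g: nx.Graph) -> bool:
    """True iff ``alpha_r == alpha_s`` for every edge (equivalently MO = 0)."""
    return compute_index_vector(g).mo == 0


def small_world_summary(g: nx.Graph) -> SmallWorldSummary:
    """Mean local clustering coefficient and average shortest-path length.

    Clustering of a vertex is triangles-through-vertex over deg*(deg-1)/2,
    defined as 0 for degree < 2; the average path length is the mean hop
    distance over unordered distinct pairs.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("small-world summary requires at least 3 vertices")
    A, _ = _to_arrays(g)
    D = _distances(A)
    v = A.shape[0]
    cc = _clustering_from_adjacency(A)
    l_apl = float(D.sum() / (v * (v - 1)))
    return SmallWorldSummary(
        c_cc=float(cc.mean()), l_apl=l_apl, v=v, mean_degree=float(A.sum() / v)
    )
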