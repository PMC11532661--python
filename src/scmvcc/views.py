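"""Shallow graph views and deep (filter-smoothed) views over cells.

Two shallow views are built from the preprocessed expression matrix: a
k-nearest-neighbour graph in Euclidean space (A_knn) and a graph thresholded
from a diffusion-map style adaptive-bandwidth Gaussian kernel (A_dm).  Each
graph yields a symmetrically normalized self-loop adjacency
H = C^{-1/2}(A + I)C^{-1/2} — a low-pass graph Laplacian filter whose
spectrum lies in [-1, 1].  Stacking t filter layers smooths the expression
matrix, F = H^t X, and pairing the two adjacencies with the two smoothed
feature matrices gives four views in two groups:

    group one:  G1 = (A_knn, F_knn),  G2 = (A_knn, F_dm)
    group two:  G3 = (A_dm,  F_knn),  G4 = (A_dm,  F_dm)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .preprocess import DegenerateInputError, ExpressionMatrix

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over cells."""

    d: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        n = self.d.shape[0]
        if self.d.ndim != 2 or self.d.shape[1] != n:
            raise ValueError("distance matrix must be square")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if np.abs(self.d - self.d.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class AffinityGraph:
    """Binary symmetric adjacency over cells with construction metadata."""

    a: np.ndarray
    method: str  # "knn" or "dm"
    k: int
    self_loops: bool = False

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        n = self.a.shape[0]
        if self.a.ndim != 2 or self.a.shape[1] != n:
            raise ValueError("adjacency must be square")
        if not np.isin(self.a, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not np.array_equal(self.a, self.a.T):
            raise ValueError("adjacency must be symmetric")
        diag = np.diag(self.a)
        if self.self_loops and not np.all(diag == 1):
            raise ValueError("self-loop adjacency must have a unit diagonal")
        if not self.self_loops and np.any(diag != 0):
            raise ValueError("adjacency must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def with_self_loops(self) -> "AffinityGraph":
        """Return the self-ring variant Â = A + I."""
        if self.self_loops:
            return self
        return AffinityGraph(self.a + np.eye(self.n), self.method, self.k, self_loops=True)

    def n_edges(self) -> int:
        """Number of undirected edges (self-loops excluded)."""
        a = self.a.copy()
        np.fill_diagonal(a, 0)
        return int(a.sum()) // 2

    def to_edge_list(self, path) -> None:
        """Write the undirected edges as a two-column TSV of 0-based indices."""
        rows, cols = np.nonzero(np.triu(self.a, k=1))
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for i, j in zip(rows, cols):
                fh.write(f"{i}\t{j}\n")

    def to_matrix_market(self, path) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(path, csr_matrix(self.a))


@dataclass
class GraphFilter:
    """Symmetrically normalized self-loop adjacency H = C^{-1/2}(A+I)C^{-1/2}."""

    h: np.ndarray
    source_method: str

    @property
    def n(self) -> int:
        return self.h.shape[0]


@dataclass
class ViewBundle:
    """The four (adjacency, filtered-features) views in their fixed order."""

    views: list[tuple[AffinityGraph, np.ndarray]]
    t: int

    #: index pairs of the two groups: group one = views 0,1; group two = 2,3
    GROUPS: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (2, 3))

    def __post_init__(self) -> None:
        if len(self.views) != 4:
            raise ValueError("a view bundle holds exactly four views")
        shapes = {f.shape for _, f in self.views}
        if len(shapes) != 1:
            raise ValueError("all view feature matrices must share one shape")
        if not np.array_equal(self.views[0][0].a, self.views[1][0].a):
            raise ValueError("views 1 and 2 must share the kNN adjacency")
        if not np.array_equal(self.views[2][0].a, self.views[3][0].a):
            raise ValueError("views 3 and 4 must share the DM adjacency")

    @property
    def n(self) -> int:
        return self.views[0][1].shape[0]

    @property
    def a_knn(self) -> AffinityGraph:
        return self.views[0][0]

    @property
    def a_dm(self) -> AffinityGraph:
        return self.views[2][0]


def pairwise_distances(x: ExpressionMatrix | np.ndarray) -> DistanceMatrix:
    """Euclidean distances between all cell pairs."""
    vals = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=np.float64)
    if vals.shape[0] < 2:
        raise DegenerateInputError("need at least two cells for pairwise distances")
    d = squareform(pdist(vals, metric="euclidean"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d)


def _directed_knn(scores: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Row-wise top-k 0/1 selection with deterministic low-index tie-break.

    ``scores`` must have the self column masked (±inf) already.
    """
    n = scores.shape[0]
    key = -scores if largest else scores
    directed = np.zeros((n, n))
    # stable sort → among equal keys the lower column index is picked first
    order = np.argsort(key, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    directed[rows, cols] = 1.0
    return directed


def build_knn_adjacency(d: DistanceMatrix, k: int) -> AffinityGraph:
    """kNN graph: each cell points at its k nearest other cells; union-symmetrized."""
    n = d.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    scores = d.d.copy()
    np.fill_diagonal(scores, np.inf)
    directed = _directed_knn(scores, k, largest=False)
    a = np.maximum(directed, directed.T)
    np.fill_diagonal(a, 0.0)
    return AffinityGraph(a=a, method="knn", k=k)


def dm_affinity(
    d: DistanceMatrix,
    k_bw: int,
    squared_distance: bool = False,
    bandwidth_mode: str = "knn_dist",
) -> np.ndarray:
    """Adaptive-bandwidth Gaussian kernel affinity in (0, 1].

    For each pair (i, j):

        a_ij = 1/2 * [ exp(-d_ij / (2 σ_k(i)^2)) + exp(-d_ij / (2 σ_k(j)^2)) ]

    where σ_k(i) is cell i's bandwidth: the distance to its k_bw-th nearest
    other cell (``bandwidth_mode="knn_dist"``) or the mean of its k_bw
    nearest distances (``"mean_knn_dist"``).  ``squared_distance=True``
    substitutes d_ij² in the numerator (the conventional Gaussian kernel).
    The diagonal is exactly 1.
    """
    n = d.n
    if not 1 <= k_bw <= n - 1:
        raise ValueError(f"k_bw must be in [1, {n - 1}], got {k_bw}")
    if bandwidth_mode not in ("knn_dist", "mean_knn_dist"):
        raise ValueError(f"unknown bandwidth_mode {bandwidth_mode!r}")
    masked = d.d.copy()
    np.fill_diagonal(masked, np.inf)
    nearest = np.sort(masked, axis=1)[:, :k_bw]
    sigma = nearest[:, -1] if bandwidth_mode == "knn_dist" else nearest.mean(axis=1)
    if np.any(sigma <= 0):
        floor = np.finfo(np.float64).eps * max(1.0, float(d.d.max()))
        logger.warning(
            "%d cells have zero kernel bandwidth (duplicate points); flooring at %.3g",
            int((sigma <= 0).sum()), floor,
        )
        sigma = np.maximum(sigma, floor)
    num = d.d**2 if squared_distance else d.d
    per_cell = np.exp(-num / (2.0 * sigma**2)[None, :])  # exp(-d_ij / 2σ_j²) at [i, j]
    aff = 0.5 * (per_cell + per_cell.T)
    np.fill_diagonal(aff, 1.0)
    return aff


def build_dm_adjacency(affinity: np.ndarray, k: int) -> AffinityGraph:
    """Threshold the kernel affinity: k strongest neighbours per cell, union-symmetrized."""
    affinity = np.asarray(affinity, dtype=np.float64)
    n = affinity.shape[0]
    if affinity.ndim != 2 or affinity.shape[1] != n:
        raise ValueError("affinity must be square")
    if np.abs(affinity - affinity.T).max(initial=0.0) > _SYM_TOL:
        raise ValueError("affinity must be symmetric")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    scores = affinity.copy()
    np.fill_diagonal(scores, -np.inf)
    directed = _directed_knn(scores, k, largest=True)
    a = np.maximum(directed, directed.T)
    np.fill_diagonal(a, 0.0)
    return AffinityGraph(a=a, method="dm", k=k)


def normalized_adjacency(a: np.ndarray) -> np.ndarray:
    """C^{-1/2}(A + I)C^{-1/2} for a zero-diagonal 0/1 adjacency A."""
    a_hat = a + np.eye(a.shape[0])
    inv_sqrt_deg = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * np.outer(inv_sqrt_deg, inv_sqrt_deg)


def normalized_laplacian_filter(g: AffinityGraph) -> GraphFilter:
    """The low-pass filter H = I − L̂ = C^{-1/2}(A+I)C^{-1/2}."""
    if g.self_loops:
        raise ValueError("pass the zero-diagonal adjacency; the self-loop is added internally")
    return GraphFilter(h=normalized_adjacency(g.a), source_method=g.method)


def apply_glf(h: GraphFilter, x: np.ndarray, t: int) -> np.ndarray:
    """Smooth features by t filter applications: F = H^t X."""
    if t < 1:
        raise ValueError("filter depth t must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    if h.h.shape[1] != x.shape[0]:
        raise ValueError("filter and feature shapes do not align")
    out = x
    for _ in range(t):
        out = h.h @ out
    return out


def assemble_views(
    a_knn: AffinityGraph, a_dm: AffinityGraph, x: ExpressionMatrix | np.ndarray, t: int = 4
) -> ViewBundle:
    """Build the four deep views from the two shallow graphs."""
    vals = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=np.float64)
    if a_knn.n != vals.shape[0] or a_dm.n != vals.shape[0]:
        raise ValueError("graphs and expression matrix must cover the same cells")
    f_knn = apply_glf(normalized_laplacian_filter(a_knn), vals, t)
    f_dm = apply_glf(normalized_laplacian_filter(a_dm), vals, t)
    return ViewBundle(
        views=[(a_knn, f_knn), (a_knn, f_dm), (a_dm, f_knn), (a_dm, f_dm)],
        t=t,
    )


def single_view_bundle(a_knn: AffinityGraph, x: ExpressionMatrix | np.ndarray, t: int = 4) -> ViewBundle:
    """Degenerate bundle that repeats view G1 four times (single-view ablation)."""
    vals = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=np.float64)
    f_knn = apply_glf(normalized_laplacian_filter(a_knn), vals, t)
    a_dm_copy = AffinityGraph(a_knn.a.copy(), method="dm", k=a_knn.k)
    return ViewBundle(
        views=[(a_knn, f_knn), (a_knn, f_knn), (a_dm_copy, f_knn), (a_dm_copy, f_knn)],
        t=t,
    )
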