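"""Graph primitives shared by every stage of the pipeline.

The central object is the column-stochastic affinity graph: an ``n x n``
nonnegative matrix whose *j*-th column is a probability distribution over the
other samples ("how much does sample *j* trust each neighbor"), with a zero
diagonal and — when built with a neighbor budget *k* — at most *k* nonzero
entries per column.  Laplacians, eigenvalue counting, connected components and
the Euclidean simplex projection live here because every later stage
(per-view updates, fusion, the solver) is built out of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.spatial.distance import cdist

__all__ = [
    "AffinityGraph",
    "GraphLaplacian",
    "ViewData",
    "build_laplacian",
    "count_zero_eigenvalues",
    "connected_components",
    "project_capped_simplex",
    "init_affinity",
    "COLSUM_TOL",
]

#: tolerance for "column sums to one" checks
COLSUM_TOL = 1e-9


@dataclass
class ViewData:
    """One view's feature matrix, stored features-by-samples (``d x n``).

    All views of a multiview dataset must share the same ``n`` samples in the
    same order; ``sample_ids`` carries the shared identifiers.
    """

    matrix: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"view matrix must be 2-D, got shape {self.matrix.shape}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:04d}" for i in range(self.n)]
        elif len(self.sample_ids) != self.n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.n} samples"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def d(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AffinityGraph:
    """Column-stochastic similarity graph.

    ``weights[i, j]`` is the similarity sample *j* assigns to sample *i*.
    Columns live on the probability simplex with a zero diagonal; ``k`` (when
    set) is the nominal neighbor budget per column.  The matrix may be
    asymmetric — symmetrization happens only inside Laplacian and component
    computations.
    """

    weights: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"affinity must be square, got {self.weights.shape}")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def validate(self, tol: float = COLSUM_TOL) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        w = self.weights
        if not np.all(np.isfinite(w)):
            raise ValueError("affinity contains non-finite entries")
        if (w < 0).any():
            raise ValueError("affinity contains negative entries")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ValueError("affinity diagonal is not identically zero")
        colsums = w.sum(axis=0)
        if np.abs(colsums - 1.0).max() > tol:
            j = int(np.abs(colsums - 1.0).argmax())
            raise ValueError(f"column {j} sums to {colsums[j]:.12f}, not 1")
        if self.k is not None:
            nnz = (w > 0).sum(axis=0)
            if nnz.max() > self.k:
                raise ValueError(
                    f"column has {int(nnz.max())} nonzeros, budget is k={self.k}"
                )

    def symmetrized(self) -> np.ndarray:
        return (self.weights + self.weights.T) / 2.0


@dataclass
class GraphLaplacian:
    """Symmetric PSD Laplacian ``L = D - (A + A^T)/2`` with its degree vector."""

    matrix: np.ndarray
    degree: np.ndarray


def build_laplacian(graph: AffinityGraph) -> GraphLaplacian:
    """Unnormalized Laplacian of the symmetrized graph.

    The stored graph is column-stochastic and possibly asymmetric; the
    Laplacian is always computed on ``(A + A^T)/2`` so that it is symmetric
    PSD and its zero eigenvalues count connected components.
    """
    a = graph.weights
    if (a < 0).any():
        raise ValueError("affinity contains negative entries")
    w = (a + a.T) / 2.0
    deg = w.sum(axis=0)
    lap = np.diag(deg) - w
    return GraphLaplacian(matrix=lap, degree=deg)


def count_zero_eigenvalues(lap: GraphLaplacian, tol: float = 1e-8) -> int:
    """Number of Laplacian eigenvalues below ``tol``.

    For a valid graph Laplacian this equals the number of connected
    components of the graph (zero-eigenvalue multiplicity).
    """
    m = np.asarray(lap.matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("Laplacian contains non-finite entries")
    evals = np.linalg.eigvalsh((m + m.T) / 2.0)
    return int(np.count_nonzero(evals < tol))


def connected_components(
    graph: AffinityGraph, support_tol: float = 1e-8
) -> tuple[int, np.ndarray]:
    """Components of the undirected support ``(A + A^T)/2 > support_tol``.

    Returns ``(count, labels)`` with labels contiguous in ``0..count-1``,
    renumbered by order of first appearance so the output is deterministic.
    """
    sym = graph.symmetrized()
    adj = sp.csr_matrix(sym > support_tol)
    count, raw = _csgraph_components(adj, directed=False)
    # renumber by first appearance
    order: dict[int, int] = {}
    labels = np.empty(raw.shape[0], dtype=int)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
        labels[i] = order[lab]
    return int(count), labels


def project_capped_simplex(
    v: np.ndarray, forbidden_index: int | None = None
) -> np.ndarray:
    """Euclidean projection onto the probability simplex, with one coordinate
    optionally pinned to zero.

    Solves ``argmin_s ||s - v||^2`` subject to ``s >= 0``, ``sum(s) = 1`` and
    (when given) ``s[forbidden_index] = 0``, by the standard shift-and-
    threshold rule ``s_i = (v_i + eta)_+`` with ``eta`` chosen so the active
    set sums to one.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.size
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot project a vector with non-finite entries")
    if forbidden_index is not None and n < 2:
        raise ValueError("need at least 2 coordinates to pin one to zero")

    free = np.ones(n, dtype=bool)
    if forbidden_index is not None:
        free[forbidden_index] = False
    u = v[free]

    # sort-based simplex projection on the free coordinates
    srt = np.sort(u)[::-1]
    css = np.cumsum(srt)
    idx = np.arange(1, u.size + 1)
    cond = srt + (1.0 - css) / idx > 0
    rho = int(np.nonzero(cond)[0][-1]) + 1
    eta = (1.0 - css[rho - 1]) / rho

    out = np.zeros(n)
    out[free] = np.maximum(u + eta, 0.0)
    return out


def init_affinity(
    view: ViewData, k: int, return_alpha: bool = False
) -> AffinityGraph | tuple[AffinityGraph, np.ndarray]:
    """Adaptive-neighbor initial graph from raw features.

    Each column *j* solves a regularized simplex problem over squared
    Euclidean distances: with the distances to the other samples sorted
    ascending as ``d_1 <= ... <= d_{n-1}``, the *k* nearest neighbors get

        ``s_i = (d_{k+1} - d_i) / (k d_{k+1} - sum_{l<=k} d_l)``

    and everything else is zero.  The implicit ridge strength per column,
    ``alpha_j = (k d_{k+1} - sum_{l<=k} d_l)/2``, is exactly the value that
    makes the column have *k* nonzeros; pass ``return_alpha=True`` to get it.

    Ties at the *k*-th distance break by sample index (stable sort).  If the
    *k+1*-th distance is zero (more than *k* duplicate points) weights are
    uniform over the zero-distance set; if the *k* nearest distances are all
    equal to the *k+1*-th (zero denominator) weights fall back to ``1/k``
    with a warning.
    """
    n = view.n
    if not 1 <= k <= n - 2:
        raise ValueError(f"need 1 <= k <= n-2, got k={k}, n={n}")
    x = view.matrix.T  # samples as rows for cdist
    dist = cdist(x, x, metric="sqeuclidean")
    np.maximum(dist, 0.0, out=dist)

    s = np.zeros((n, n))
    alphas = np.zeros(n)
    for j in range(n):
        d = dist[:, j].copy()
        d[j] = np.inf
        order = np.argsort(d, kind="stable")
        nn = order[:k]
        d_k1 = d[order[k]]
        if d_k1 <= 0.0:
            # > k coincident points: uniform over the whole zero-distance set
            tied = order[d[order] <= 0.0]
            s[tied, j] = 1.0 / tied.size
            alphas[j] = 0.0
            continue
        denom = k * d_k1 - d[nn].sum()
        if denom <= 0.0:
            warnings.warn(
                f"column {j}: k nearest distances all equal the (k+1)-th; "
                "using uniform weights",
                RuntimeWarning,
                stacklevel=2,
            )
            s[nn, j] = 1.0 / k
            alphas[j] = 0.0
        else:
            s[nn, j] = (d_k1 - d[nn]) / denom
            alphas[j] = denom / 2.0
    graph = AffinityGraph(weights=s, k=k)
    if return_alpha:
        return graph, alphas
    return graph
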