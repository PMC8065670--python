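"""Per-view alternating updates: spectral embeddings and affinity refreshes.

Each view alternates between two closed-form moves.  The embedding ``F``
(``n x c``, orthonormal columns) minimizes ``Tr(F^T L F)`` — by the Ky Fan
theorem this is spanned by the eigenvectors of the ``c`` smallest Laplacian
eigenvalues, and the achieved trace equals their sum.  The affinity refresh
re-solves each column's regularized simplex problem, now penalizing
embedding distances ``p_ij = ||f_i - f_j||^2`` and pulling toward the
current consensus column with strength ``w`` (the view's weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .graph import AffinityGraph, GraphLaplacian, project_capped_simplex

__all__ = ["Embedding", "update_embedding", "embedding_distances", "update_affinity"]

#: positive floor for the per-column ridge scale when the exact-k rule degenerates
DELTA_FLOOR = 1e-12


@dataclass
class Embedding:
    """``n x c`` matrix with orthonormal columns (spectral embedding)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("embedding must be 2-D")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def c(self) -> int:
        return self.matrix.shape[1]


def update_embedding(lap: GraphLaplacian, c: int) -> Embedding:
    """Eigenvectors of the ``c`` smallest Laplacian eigenvalues.

    Deterministic up to eigenvalue degeneracy: eigenvalues come back in
    ascending order and each eigenvector's sign is fixed so its largest-
    magnitude entry (first such entry on ties) is positive.
    """
    m = np.asarray(lap.matrix, dtype=float)
    n = m.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds n={n}")
    try:
        _, vecs = scipy.linalg.eigh((m + m.T) / 2.0, subset_by_index=[0, c - 1])
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise ArithmeticError(f"eigensolver failed on {n}x{n} Laplacian: {exc}")
    for col in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, col])))
        if vecs[i, col] < 0:
            vecs[:, col] = -vecs[:, col]
    return Embedding(matrix=vecs)


def embedding_distances(emb: Embedding) -> np.ndarray:
    """Pairwise squared Euclidean distances between embedding rows.

    Satisfies the trace identity ``Tr(F^T L F) = (1/2) sum_ij p_ij a_ij`` for
    the Laplacian of any symmetric adjacency ``a``.
    """
    p = cdist(emb.matrix, emb.matrix, metric="sqeuclidean")
    p = (p + p.T) / 2.0
    np.maximum(p, 0.0, out=p)
    np.fill_diagonal(p, 0.0)
    return p


def update_affinity(
    p: np.ndarray,
    z: AffinityGraph,
    w: float,
    k: int,
    return_alpha: bool = False,
) -> AffinityGraph | tuple[AffinityGraph, np.ndarray]:
    """Closed-form refresh of one view's affinity graph.

    Column *j* minimizes

        ``sum_i p_ij s_ij + alpha_j ||s_j||^2 + w ||z_j - s_j||^2``

    over the zero-diagonal simplex.  Writing ``delta_j = alpha_j + w``, the
    minimizer is the simplex projection of ``(w z_j - p_j/2)/delta_j``; the
    per-column ``delta_j`` is set by the exact-*k* sparsity rule: rank
    candidates ``i != j`` by cost ``g_i = p_ij/2 - w z_ij`` ascending, keep
    the best *k*, and choose

        ``delta_j = k g_{(k+1)} - sum_{l<=k} g_{(l)}``

    which places the *(k+1)*-th candidate exactly at the zero threshold.
    ``alpha`` is therefore never a user parameter.  If the rule yields a
    non-positive ``delta`` (consensus mass concentrated outside the top *k*)
    it is clamped to a small positive floor with a warning.
    """
    if w <= 0:
        raise ValueError(f"view weight must be positive, got {w}")
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    if not 1 <= k <= n - 2:
        raise ValueError(f"need 1 <= k <= n-2, got k={k}, n={n}")
    zw = z.weights

    s = np.zeros((n, n))
    alphas = np.zeros(n)
    for j in range(n):
        g = p[:, j] / 2.0 - w * zw[:, j]
        g[j] = np.inf
        order = np.argsort(g, kind="stable")
        top = order[:k]
        g_k1 = g[order[k]]
        delta = k * g_k1 - g[top].sum()
        if delta <= DELTA_FLOOR:
            warnings.warn(
                f"column {j}: exact-k rule gave delta={delta:.3e}; clamping",
                RuntimeWarning,
                stacklevel=2,
            )
            delta = DELTA_FLOOR
        # solve on the selected support; off-support coordinates stay zero.
        # The simplex projection is invariant to adding a constant, so
        # center the scores before dividing by delta — keeps the tiny-delta
        # (clamped) case numerically exact.
        a = w * zw[top, j] - p[top, j] / 2.0
        sub = project_capped_simplex((a - a.max()) / delta, forbidden_index=None)
        s[top, j] = sub
        alphas[j] = delta - w
    graph = AffinityGraph(weights=s, k=k)
    if return_alpha:
        return graph, alphas
    return graph
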