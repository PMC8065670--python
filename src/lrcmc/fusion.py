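"""Consensus-graph learning: self-tuned view weights and the fused graph.

The consensus graph ``Z`` is the single affinity graph all views agree on.
Each view's weight is inversely proportional to the Frobenius distance
between its graph and ``Z`` (views that already agree with the consensus
count for more), and the consensus column update is a simplex projection of
the weighted average of view columns shifted by the fused-embedding
distances scaled by the rank-constraint strength ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import AffinityGraph, build_laplacian, project_capped_simplex
from .view_update import Embedding, update_embedding

__all__ = [
    "ViewWeights",
    "update_weights",
    "update_consensus",
    "update_fused_embedding",
]

#: floor for the Frobenius distance in the inverse-distance weights
DIST_FLOOR = 1e-12


@dataclass
class ViewWeights:
    """Positive per-view weights measuring agreement with the consensus."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.w.size == 0 or not np.all(np.isfinite(self.w)) or (self.w <= 0).any():
            raise ValueError("view weights must be positive and finite")

    @property
    def m(self) -> int:
        return self.w.size


def update_weights(
    z: AffinityGraph, views: list[AffinityGraph], exponent: int = 1
) -> ViewWeights:
    """Inverse-distance view weights ``w_v = 1 / (2 ||Z - S^v||_F^exponent)``.

    ``exponent=1`` (default) is the self-weighted fixed point of the
    implicit sum-of-Frobenius-distances objective; ``exponent=2`` is the
    squared-distance variant.  Distances below ``1e-12`` are floored so a
    view identical to the consensus gets the largest finite weight.
    """
    if exponent not in (1, 2):
        raise ValueError(f"weight exponent must be 1 or 2, got {exponent}")
    dists = np.array(
        [np.linalg.norm(z.weights - s.weights, "fro") for s in views]
    )
    dists = np.maximum(dists, DIST_FLOOR)
    return ViewWeights(w=1.0 / (2.0 * dists**exponent))


def update_consensus(
    views: list[AffinityGraph],
    weights: ViewWeights,
    q: np.ndarray,
    beta: float,
) -> AffinityGraph:
    """Closed-form consensus update.

    Column *j* minimizes ``sum_v w_v ||z_j - s_j^v||^2 + beta sum_i q_ij z_ij``
    over the zero-diagonal simplex, where ``q_ij`` are squared distances
    between fused-embedding rows.  The minimizer is

        ``proj_simplex( (sum_v w_v s_j^v - (beta/2) q_j) / sum_v w_v )``

    with the diagonal coordinate pinned to zero.  The consensus is not
    re-sparsified to *k* entries; sparsity emerges from the projection.
    """
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    if len(views) != weights.m:
        raise ValueError(f"{len(views)} graphs but {weights.m} weights")
    wsum = weights.w.sum()
    n = views[0].n
    mean = np.zeros((n, n))
    for wv, s in zip(weights.w, views):
        mean += wv * s.weights
    target = (mean - (beta / 2.0) * np.asarray(q, dtype=float)) / wsum
    z = np.zeros((n, n))
    for j in range(n):
        z[:, j] = project_capped_simplex(target[:, j], forbidden_index=j)
    return AffinityGraph(weights=z, k=None)


def update_fused_embedding(z: AffinityGraph, c: int) -> Embedding:
    """Spectral embedding of the consensus graph (``c`` smallest eigenvectors
    of its Laplacian); delegates to :func:`update_embedding`."""
    return update_embedding(build_laplacian(z), c)
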