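"""The LRCMC alternating optimizer.

Given ``m`` feature matrices for the same ``n`` samples, the solver learns a
``k``-sparse adaptive-neighbor affinity graph per view, fuses them into a
weighted consensus graph ``Z``, and drives the rank of ``Z``'s Laplacian to
``n - c`` so that ``Z`` falls apart into exactly ``c`` connected components —
the clusters.  One iteration cycles five closed-form updates (per-view
affinities, per-view embeddings, view weights, consensus, fused embedding);
the rank-constraint strength ``beta`` is adapted dynamically (halved when
``Z`` has too many components, doubled when too few).  The pipeline is fully
deterministic: identical inputs and configuration give bit-identical labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .fusion import (
    ViewWeights,
    update_consensus,
    update_fused_embedding,
    update_weights,
)
from .graph import (
    AffinityGraph,
    ViewData,
    build_laplacian,
    connected_components,
    init_affinity,
    project_capped_simplex,
)
from .view_update import (
    Embedding,
    embedding_distances,
    update_affinity,
    update_embedding,
)

__all__ = ["LRCMCConfig", "SolverState", "ClusterLabels", "initialize", "step",
           "adapt_beta", "fit"]


@dataclass
class LRCMCConfig:
    """Solver configuration.

    Only ``c`` (target cluster count) and ``k`` (neighbors per column) are
    required; ``beta0`` rarely needs tuning because the doubling/halving rule
    finds the right scale on its own.
    """

    c: int
    k: int
    beta0: float = 1.0
    beta_min: float = 2.0**-20
    beta_max: float = 2.0**20
    max_iter: int = 100
    support_tol: float = 1e-8
    seed: int = 0
    weight_exponent: int = 1
    min_cluster_size: int | None = None

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError(f"need at least 2 clusters, got c={self.c}")
        if self.k < 1:
            raise ValueError(f"need at least 1 neighbor, got k={self.k}")
        if not 0 < self.beta_min <= self.beta_max:
            raise ValueError("need 0 < beta_min <= beta_max")
        if not self.beta_min <= self.beta0 <= self.beta_max:
            raise ValueError(
                f"beta0={self.beta0} outside [{self.beta_min}, {self.beta_max}]"
            )
        if self.weight_exponent not in (1, 2):
            raise ValueError("weight_exponent must be 1 or 2")


@dataclass
class ClusterLabels:
    """Final labels, contiguous in ``0..n_clusters-1`` by first appearance."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()


@dataclass
class SolverState:
    """Everything the alternating loop carries between iterations."""

    views: list[ViewData]
    config: LRCMCConfig
    graphs: list[AffinityGraph]
    embeddings: list[Embedding]
    alphas: list[np.ndarray]
    weights: ViewWeights
    z: AffinityGraph
    u: Embedding
    beta: float
    iteration: int = 0
    component_count: int = 0
    converged: bool = False
    small_clusters: bool = False
    objective_trace: list[float] = field(default_factory=list)
    beta_trace: list[float] = field(default_factory=list)
    component_trace: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.views[0].n

    @property
    def m(self) -> int:
        return len(self.views)


def _check_views(views: list[ViewData], config: LRCMCConfig) -> int:
    if not views:
        raise ValueError("need at least one view")
    n = views[0].n
    for i, v in enumerate(views):
        if v.n != n:
            raise ValueError(f"view {i} has {v.n} samples, view 0 has {n}")
    if not config.c <= n - 1:
        raise ValueError(f"c={config.c} too large for n={n}")
    if not config.k <= n - 2:
        raise ValueError(f"k={config.k} too large for n={n}")
    return n


def objective(state: SolverState, include_ridge: bool = False) -> float:
    """Joint objective at the current variables.

    Sums, over views, ``2 Tr(F^T L F) + w_v ||Z - S^v||_F^2`` plus the rank
    term ``2 beta Tr(U^T L_Z U)`` (via the trace identity
    ``2 Tr(F^T L F) = sum_ij p_ij s_ij``).  The ridge terms
    ``sum_j alpha_j ||s_j||^2`` are omitted by default: each column's ridge
    strength is re-calibrated every iteration by the exact-*k* sparsity
    rule, so including them makes values incomparable across iterations;
    pass ``include_ridge=True`` for the full value at the current implicit
    strengths.
    """
    total = 0.0
    zw = state.z.weights
    for s, f, a, wv in zip(
        state.graphs, state.embeddings, state.alphas, state.weights.w
    ):
        p = embedding_distances(f)
        total += float(np.sum(p * s.weights))
        if include_ridge:
            total += float(np.sum(a * np.sum(s.weights**2, axis=0)))
        total += wv * float(np.linalg.norm(zw - s.weights, "fro") ** 2)
    q = embedding_distances(state.u)
    total += state.beta * float(np.sum(q * zw))
    return total


def initialize(views: list[ViewData], config: LRCMCConfig) -> SolverState:
    """Build the starting state.

    Per-view graphs come from the adaptive-neighbor rule on raw feature
    distances, embeddings from their Laplacians, weights are uniform
    ``1/m``, and the consensus starts as the (already feasible) weighted
    average of the view graphs, projected columnwise for safety.
    """
    n = _check_views(views, config)
    graphs: list[AffinityGraph] = []
    alphas: list[np.ndarray] = []
    for v in views:
        g, a = init_affinity(v, config.k, return_alpha=True)
        graphs.append(g)
        alphas.append(a)
    embeddings = [
        update_embedding(build_laplacian(g), config.c) for g in graphs
    ]
    m = len(views)
    weights = ViewWeights(w=np.full(m, 1.0 / m))
    mix = np.zeros((n, n))
    for wv, g in zip(weights.w, graphs):
        mix += wv * g.weights
    zw = np.zeros((n, n))
    for j in range(n):
        zw[:, j] = project_capped_simplex(mix[:, j], forbidden_index=j)
    z = AffinityGraph(weights=zw, k=None)
    u = update_fused_embedding(z, config.c)
    count, _ = connected_components(z, config.support_tol)
    return SolverState(
        views=views,
        config=config,
        graphs=graphs,
        embeddings=embeddings,
        alphas=alphas,
        weights=weights,
        z=z,
        u=u,
        beta=float(np.clip(config.beta0, config.beta_min, config.beta_max)),
        component_count=count,
    )


def step(state: SolverState) -> SolverState:
    """One full cycle of the five closed-form updates (in place).

    Order: per-view affinities (using current embeddings, weights and
    consensus) → per-view embeddings → view weights → consensus → fused
    embedding.  Appends the objective, beta and component count to the
    traces.
    """
    cfg = state.config
    try:
        for v in range(state.m):
            p = embedding_distances(state.embeddings[v])
            g, a = update_affinity(
                p, state.z, float(state.weights.w[v]), cfg.k, return_alpha=True
            )
            state.graphs[v] = g
            state.alphas[v] = a
        for v in range(state.m):
            state.embeddings[v] = update_embedding(
                build_laplacian(state.graphs[v]), cfg.c
            )
        state.weights = update_weights(
            state.z, state.graphs, exponent=cfg.weight_exponent
        )
        q = embedding_distances(state.u)
        state.z = update_consensus(state.graphs, state.weights, q, state.beta)
        state.u = update_fused_embedding(state.z, cfg.c)
    except (ValueError, ArithmeticError) as exc:
        raise type(exc)(f"iteration {state.iteration}: {exc}") from exc
    state.iteration += 1
    state.component_count, _ = connected_components(state.z, cfg.support_tol)
    state.objective_trace.append(objective(state))
    state.beta_trace.append(state.beta)
    state.component_trace.append(state.component_count)
    return state


def adapt_beta(state: SolverState, config: LRCMCConfig) -> SolverState:
    """Dynamic rank-constraint strength.

    Too many components means the rank penalty is over-shattering the graph:
    halve ``beta``.  Too few means it is too weak to cut the graph: double
    it.  On target, leave it alone.  Always clamped to the configured range.
    """
    if state.component_count > config.c:
        state.beta /= 2.0
    elif state.component_count < config.c:
        state.beta *= 2.0
    state.beta = float(np.clip(state.beta, config.beta_min, config.beta_max))
    return state


def _merge_components(sym: np.ndarray, labels: np.ndarray, count: int, c: int) -> np.ndarray:
    """Repeatedly merge the two components joined by the strongest
    cross-component similarity until ``c`` remain."""
    labels = labels.copy()
    while count > c:
        best = (-1.0, 0, 1)
        for a in range(count):
            ia = labels == a
            for b in range(a + 1, count):
                ib = labels == b
                link = float(sym[np.ix_(ia, ib)].max(initial=0.0))
                if link > best[0]:
                    best = (link, a, b)
        _, a, b = best
        labels[labels == b] = a
        labels[labels > b] -= 1
        count -= 1
    return labels


def _split_components(
    sym: np.ndarray, labels: np.ndarray, count: int, c: int
) -> np.ndarray:
    """Repeatedly split the largest component by spectral bisection of its
    consensus submatrix until ``c`` exist."""
    labels = labels.copy()
    while count < c:
        sizes = np.bincount(labels, minlength=count)
        big = int(np.argmax(sizes))
        idx = np.nonzero(labels == big)[0]
        if idx.size < 2:
            raise ValueError("cannot split a singleton component further")
        sub = sym[np.ix_(idx, idx)]
        lap = np.diag(sub.sum(axis=0)) - sub
        _, vecs = scipy.linalg.eigh(lap, subset_by_index=[0, min(1, idx.size - 1)])
        fiedler = vecs[:, -1]
        side = fiedler > np.median(fiedler)
        if side.all() or not side.any():
            side = np.zeros(idx.size, dtype=bool)
            side[: idx.size // 2] = True
        labels[idx[side]] = count
        count += 1
    return labels


def extract_labels(state: SolverState) -> ClusterLabels:
    """Read cluster labels off the consensus graph's connected components,
    forcing exactly ``c`` clusters by merge/split if the solver stopped off
    target (only happens on non-converged runs)."""
    cfg = state.config
    count, labels = connected_components(state.z, cfg.support_tol)
    if count != cfg.c:
        sym = state.z.symmetrized()
        if count > cfg.c:
            labels = _merge_components(sym, labels, count, cfg.c)
        else:
            labels = _split_components(sym, labels, count, cfg.c)
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return ClusterLabels(labels=out, n_clusters=int(out.max()) + 1)


def fit(
    views: list[ViewData], config: LRCMCConfig
) -> tuple[ClusterLabels, SolverState]:
    """Run the full alternating optimization.

    Iterates ``step`` + ``adapt_beta`` until the consensus graph has exactly
    ``c`` connected components on two consecutive iterations (guards against
    beta flip-flop) or ``max_iter`` is reached.  A run that ends off target
    is flagged ``converged=False`` and labels are forced to ``c`` clusters
    by merge/split — never silently.
    """
    state = initialize(views, config)
    hits = 0
    for _ in range(config.max_iter):
        state = step(state)
        if state.component_count == config.c:
            hits += 1
        else:
            hits = 0
        if hits >= 2:
            state.converged = True
            break
        state = adapt_beta(state, config)
    labels = extract_labels(state)
    if config.min_cluster_size:
        sizes = np.bincount(labels.labels, minlength=labels.n_clusters)
        if sizes.min() < config.min_cluster_size:
            state.small_clusters = True
            warnings.warn(
                f"smallest cluster has {int(sizes.min())} samples "
                f"(< {config.min_cluster_size})",
                RuntimeWarning,
                stacklevel=2,
            )
    return labels, state
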