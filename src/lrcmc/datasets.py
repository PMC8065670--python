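"""Synthetic multiview data with known ground truth.

The generator emulates the structure the clustering model assumes: the same
``n`` samples observed in ``m`` feature spaces, each view placing ``c``
well-separated cluster centers on an orthogonal frame (so the separation /
noise ratio is a single controllable number) and adding independent
isotropic Gaussian noise.  A view can be *corrupted* — its cluster
assignment is shuffled before generation, so it retains internal cluster
structure but carries no signal about the true labels; such views should be
down-weighted by the fusion step.

It makes no attempt at realistic omics marginals (counts, methylation
betas): it is a geometry fixture, not a biology simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ViewData
from .solver import ClusterLabels

__all__ = ["BlobSpec", "make_multiview_blobs", "make_worked_fixture"]


@dataclass
class BlobSpec:
    """Parameters of the multiview blob generator.

    ``separation`` is the scale of the orthogonal center frame per view
    (pairwise center distance is ``separation * sqrt(2)``); ``noise_sd`` is
    the per-view isotropic noise.  Defaults give a separation/noise ratio of
    10, the well-separated regime in which perfect recovery is expected.
    """

    n_per_cluster: int = 30
    c: int = 3
    m: int = 3
    dims: tuple[int, ...] | None = None
    separation: float = 10.0
    noise_sd: tuple[float, ...] | float = 1.0
    corrupt_views: frozenset[int] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims is None:
            self.dims = tuple([10] * self.m)
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != self.m:
            raise ValueError(f"{len(self.dims)} dims for {self.m} views")
        if any(d < 1 for d in self.dims):
            raise ValueError("all view dimensions must be >= 1")
        if np.isscalar(self.noise_sd):
            self.noise_sd = tuple([float(self.noise_sd)] * self.m)
        self.noise_sd = tuple(float(s) for s in self.noise_sd)
        if len(self.noise_sd) != self.m:
            raise ValueError(f"{len(self.noise_sd)} noise sds for {self.m} views")
        if self.separation <= 0 or any(s <= 0 for s in self.noise_sd):
            raise ValueError("separation and noise_sd must be positive")
        self.corrupt_views = frozenset(int(v) for v in self.corrupt_views)
        if any(not 0 <= v < self.m for v in self.corrupt_views):
            raise ValueError("corrupt view index out of range")


def _centers(rng: np.random.Generator, d: int, c: int, scale: float) -> np.ndarray:
    """``d x c`` center matrix with pairwise distances >= scale."""
    if d >= c:
        q, _ = np.linalg.qr(rng.standard_normal((d, c)))
        return scale * q[:, :c]
    # low-dimensional view: random directions rescaled to the target
    # minimum separation
    g = rng.standard_normal((d, c))
    dists = np.sqrt(
        np.sum((g[:, :, None] - g[:, None, :]) ** 2, axis=0)
    )
    np.fill_diagonal(dists, np.inf)
    dmin = dists.min()
    if dmin <= 0:
        raise ValueError("degenerate random centers; use a different seed")
    return (scale * np.sqrt(2.0) / dmin) * g


def make_multiview_blobs(spec: BlobSpec) -> tuple[list[ViewData], ClusterLabels]:
    """Draw ``c`` balanced Gaussian clusters observed in ``m`` views.

    Deterministic under ``spec.seed``.  Views listed in ``corrupt_views``
    are generated from an independently shuffled copy of the labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_cluster * spec.c
    labels = np.repeat(np.arange(spec.c), spec.n_per_cluster)
    sample_ids = [f"s{i:04d}" for i in range(n)]
    views: list[ViewData] = []
    for v in range(spec.m):
        d = spec.dims[v]
        centers = _centers(rng, d, spec.c, spec.separation)
        view_labels = labels
        if v in spec.corrupt_views:
            view_labels = rng.permutation(labels)
        x = centers[:, view_labels] + spec.noise_sd[v] * rng.standard_normal((d, n))
        views.append(ViewData(matrix=x, sample_ids=list(sample_ids)))
    return views, ClusterLabels(labels=labels, n_clusters=spec.c)


# ---------------------------------------------------------------------------
# frozen worked fixture: n=12, c=3, m=2.  Values were drawn once from a
# seeded blob generator (three clusters of four samples, separation/noise
# ratio 16) and rounded to 4 decimals; they are committed as literals so
# regression tests are bit-exact on every platform.

_FIXTURE_VIEW1 = [
    [8.2252, 7.6099, 8.1035, 7.6105, -3.4738, -4.8505, -3.1214, -2.3843,
     -4.1868, -4.1915, -4.6026, -4.2646],
    [0.4026, 1.1752, 0.1417, 0.1252, 7.026, 6.341, 6.8893, 7.4824,
     -7.6966, -6.6705, -6.9727, -6.8176],
]

_FIXTURE_VIEW2 = [
    [-0.591, -0.5516, -0.5571, -1.0254, 6.6525, 8.2226, 8.6349, 7.3544,
     1.4824, 0.468, 0.122, 1.2567],
    [-4.8165, -4.7034, -5.0724, -4.7238, -1.3374, -1.3728, -1.5554, -0.6639,
     5.6387, 6.0138, 6.1689, 5.2259],
    [6.3541, 6.2581, 6.6286, 6.3137, -0.1789, 0.5903, -0.5309, -0.596,
     5.6701, 4.98, 4.4601, 4.5366],
]

_FIXTURE_LABELS = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]


def make_worked_fixture() -> tuple[list[ViewData], ClusterLabels]:
    """Tiny frozen instance (n=12, c=3, m=2) with hard-coded matrices.

    Used for bit-exact regression tests of every update; the generating
    labels are four samples per cluster in order.
    """
    ids = [f"s{i:04d}" for i in range(12)]
    views = [
        ViewData(matrix=np.array(_FIXTURE_VIEW1), sample_ids=list(ids)),
        ViewData(matrix=np.array(_FIXTURE_VIEW2), sample_ids=list(ids)),
    ]
    return views, ClusterLabels(labels=np.array(_FIXTURE_LABELS), n_clusters=3)
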