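"""Clustering quality metrics: ACC, NMI and purity.

ACC matches predicted clusters to true classes one-to-one by solving the
assignment problem on the contingency table (Hungarian algorithm), so it is
invariant to relabeling of either partition.  NMI is the mutual information
of the two partitions normalized by their entropies; the normalization is
configurable because the literature is split between the geometric-mean,
max and arithmetic-mean conventions.  Purity averages the dominant true-
class fraction over predicted clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["MetricReport", "contingency", "accuracy", "nmi", "purity", "evaluate",
           "aggregate"]


@dataclass
class MetricReport:
    """ACC / NMI / purity for one run, all in [0, 1]."""

    acc: float
    nmi: float
    purity: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency(true_labels, pred_labels) -> np.ndarray:
    """Contingency table, true classes as rows, predicted clusters as
    columns."""
    t = _as_codes(true_labels)
    p = _as_codes(pred_labels)
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    table = np.zeros((t.max() + 1, p.max() + 1), dtype=int)
    np.add.at(table, (t, p), 1)
    return table


def accuracy(true_labels, pred_labels) -> float:
    """Fraction correct under the best one-to-one cluster-to-class map.

    Solved by maximum-weight assignment on the contingency table; unequal
    cluster/class counts are handled naturally (the assignment is over the
    smaller side)."""
    table = contingency(true_labels, pred_labels)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / float(table.sum())


def nmi(true_labels, pred_labels, normalization: str = "sqrt") -> float:
    """Normalized mutual information with natural-log entropies.

    ``normalization`` is one of ``sqrt`` (geometric mean, default), ``max``
    or ``arithmetic``.  If both partitions are trivial (single cluster) the
    partitions are identical and the score is 1; if exactly one is trivial
    there is no shared information and the score is 0.
    """
    table = contingency(true_labels, pred_labels).astype(float)
    n = table.sum()
    pt = table.sum(axis=1) / n
    pp = table.sum(axis=0) / n
    h_t = -np.sum(pt[pt > 0] * np.log(pt[pt > 0]))
    h_p = -np.sum(pp[pp > 0] * np.log(pp[pp > 0]))
    if h_t == 0.0 and h_p == 0.0:
        return 1.0
    if h_t == 0.0 or h_p == 0.0:
        return 0.0
    pj = table / n
    mask = pj > 0
    outer = np.outer(pt, pp)
    mi = float(np.sum(pj[mask] * np.log(pj[mask] / outer[mask])))
    if normalization == "sqrt":
        denom = float(np.sqrt(h_t * h_p))
    elif normalization == "max":
        denom = float(max(h_t, h_p))
    elif normalization == "arithmetic":
        denom = float((h_t + h_p) / 2.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(np.clip(mi / denom, 0.0, 1.0))


def purity(true_labels, pred_labels) -> float:
    """Mean dominant-class fraction over predicted clusters:
    ``(1/n) sum_clusters max_class count``."""
    table = contingency(true_labels, pred_labels)
    return float(table.max(axis=0).sum()) / float(table.sum())


def evaluate(true_labels, pred_labels, normalization: str = "sqrt") -> MetricReport:
    """All three metrics at once."""
    t = np.asarray(true_labels).ravel()
    return MetricReport(
        acc=accuracy(true_labels, pred_labels),
        nmi=nmi(true_labels, pred_labels, normalization=normalization),
        purity=purity(true_labels, pred_labels),
        n=int(t.size),
    )


def aggregate(reports: list[MetricReport]) -> dict:
    """Mean and standard deviation of each metric over repeated runs."""
    out: dict = {"runs": len(reports)}
    for name in ("acc", "nmi", "purity"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=0))
    return out
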