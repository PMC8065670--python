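"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the code it verifies:
brute-force active-set enumeration for the simplex projection, a generic
SLSQP solve for the columnwise quadratic programs, exhaustive permutation
search for clustering accuracy, and plug-in contingency-table formulas for
NMI and purity.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def brute_simplex_projection(v: np.ndarray, forbidden: int | None = None) -> np.ndarray:
    """Projection onto the simplex by enumerating every candidate support
    and checking the KKT conditions.  Exponential — small n only."""
    v = np.asarray(v, dtype=float)
    n = v.size
    free = [i for i in range(n) if i != forbidden]
    best, best_val = None, np.inf
    for r in range(1, len(free) + 1):
        for support in itertools.combinations(free, r):
            lam = (1.0 - v[list(support)].sum()) / r
            s = np.zeros(n)
            s[list(support)] = v[list(support)] + lam
            if (s[list(support)] < -1e-12).any():
                continue
            # KKT: excluded free coordinates must not want in
            ok = all(v[i] + lam <= 1e-12 for i in free if i not in support)
            if not ok:
                continue
            val = np.sum((s - v) ** 2)
            if val < best_val - 1e-15:
                best, best_val = s, val
    assert best is not None
    return np.maximum(best, 0.0)


def slsqp_column_qp(
    quad: np.ndarray | float, lin: np.ndarray, forbidden: int
) -> np.ndarray:
    """Generic solver for ``min 0.5*quad*||s||^2 + lin.s`` on the
    zero-diagonal simplex (SLSQP with equality + box constraints)."""
    lin = np.asarray(lin, dtype=float)
    n = lin.size
    # scale-normalize (argmin unchanged) so SLSQP's tolerances behave
    scale = max(abs(quad), float(np.abs(lin).max()), 1.0)
    quad = quad / scale
    lin = lin / scale

    def fun(s):
        return 0.5 * quad * float(s @ s) + float(lin @ s)

    def jac(s):
        return quad * s + lin

    bounds = [(0.0, 1.0)] * n
    bounds[forbidden] = (0.0, 0.0)
    cons = [{"type": "eq", "fun": lambda s: s.sum() - 1.0,
             "jac": lambda s: np.ones(n)}]
    starts = [np.full(n, 1.0 / (n - 1))]
    rng = np.random.default_rng(0)
    for _ in range(4):
        x0 = rng.random(n)
        x0[forbidden] = 0.0
        starts.append(x0 / x0.sum())
    best, best_val = None, np.inf
    for x0 in starts:
        x0 = x0.copy()
        x0[forbidden] = 0.0
        res = minimize(fun, x0, jac=jac, bounds=bounds, constraints=cons,
                       method="SLSQP",
                       options={"maxiter": 1000, "ftol": 1e-14})
        if res.success and fun(res.x) < best_val:
            best, best_val = res.x, fun(res.x)
    assert best is not None, "SLSQP failed from every start"
    return np.maximum(best, 0.0)


def slsqp_affinity_column(
    p_col: np.ndarray, z_col: np.ndarray, w: float, alpha: float, j: int
) -> np.ndarray:
    """Generic solve of one affinity column problem
    ``min p.s + alpha ||s||^2 + w ||z - s||^2`` on the zero-diagonal simplex."""
    # expand: (alpha + w) ||s||^2 + (p - 2 w z).s + const
    return slsqp_column_qp(2.0 * (alpha + w), p_col - 2.0 * w * z_col, j)


def slsqp_consensus_column(
    s_cols: list[np.ndarray], weights: np.ndarray, q_col: np.ndarray,
    beta: float, j: int
) -> np.ndarray:
    """Generic solve of one consensus column problem
    ``min sum_v w_v ||z - s^v||^2 + beta q.z`` on the zero-diagonal simplex."""
    wsum = float(np.sum(weights))
    lin = beta * q_col - 2.0 * sum(w * s for w, s in zip(weights, s_cols))
    return slsqp_column_qp(2.0 * wsum, lin, j)


def exhaustive_accuracy(true_labels, pred_labels) -> float:
    """Best-match accuracy by trying every one-to-one cluster-to-class map."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    t_classes = list(np.unique(t))
    p_classes = list(np.unique(p))
    big, small = (t_classes, p_classes) if len(t_classes) >= len(p_classes) \
        else (p_classes, t_classes)
    best = 0
    for perm in itertools.permutations(big, len(small)):
        mapping = dict(zip(small, perm))
        if len(t_classes) >= len(p_classes):
            hits = sum(int(mapping[pi] == ti) for ti, pi in zip(t, p))
        else:
            hits = sum(int(mapping[ti] == pi) for ti, pi in zip(t, p))
        best = max(best, hits)
    return best / t.size


def contingency_table(true_labels, pred_labels) -> np.ndarray:
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    rows = {c: i for i, c in enumerate(np.unique(t))}
    cols = {c: i for i, c in enumerate(np.unique(p))}
    table = np.zeros((len(rows), len(cols)))
    for ti, pi in zip(t, p):
        table[rows[ti], cols[pi]] += 1
    return table


def plugin_nmi(true_labels, pred_labels) -> float:
    """NMI from the printed contingency table, geometric-mean normalization."""
    table = contingency_table(true_labels, pred_labels)
    n = table.sum()
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * np.log(nij * n / (table[i].sum() * table[:, j].sum()))
    def ent(counts):
        pr = counts[counts > 0] / n
        return -np.sum(pr * np.log(pr))
    h_t, h_p = ent(table.sum(axis=1)), ent(table.sum(axis=0))
    if h_t == 0 and h_p == 0:
        return 1.0
    if h_t == 0 or h_p == 0:
        return 0.0
    return mi / np.sqrt(h_t * h_p)


def naive_purity(true_labels, pred_labels) -> float:
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    total = 0
    for cluster in np.unique(p):
        members = t[p == cluster]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / t.size


def random_affinity(rng: np.random.Generator, n: int, k: int | None = None) -> np.ndarray:
    """Random column-stochastic zero-diagonal matrix (optionally k-sparse)."""
    w = rng.random((n, n))
    np.fill_diagonal(w, 0.0)
    if k is not None:
        for j in range(n):
            order = np.argsort(-w[:, j], kind="stable")
            w[order[k:], j] = 0.0
    w /= w.sum(axis=0, keepdims=True)
    return w
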