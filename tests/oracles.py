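"""Naive reference implementations used as independent oracles in tests.

Everything here is written as literal per-element loops or exhaustive
enumeration, deliberately independent of the vectorized implementations in
the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def ntxent_columns_loop(za: np.ndarray, zb: np.ndarray, tau: float) -> float:
    """Literal per-column double-loop evaluation of the column contrast."""
    c = za.shape[1]
    total = 0.0
    for i in range(c):
        num = np.exp(cosine(za[:, i], zb[:, i]) / tau)
        den = sum(np.exp(cosine(za[:, i], za[:, j]) / tau) for j in range(c) if j != i)
        den += sum(np.exp(cosine(za[:, i], zb[:, j]) / tau) for j in range(c))
        total += -np.log(num / den)
    return total / c


def group_contrastive_loop(z1, z2, z3, z4, tau: float) -> float:
    l1 = 0.5 * (ntxent_columns_loop(z1, z2, tau) + ntxent_columns_loop(z2, z1, tau))
    l2 = 0.5 * (ntxent_columns_loop(z3, z4, tau) + ntxent_columns_loop(z4, z3, tau))
    return l1 + l2


def structural_loop(s: np.ndarray, a_hat: np.ndarray) -> float:
    """Indicator-split double loop: (s-1)^2 on edges of Â, s^2 elsewhere."""
    n = s.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if a_hat[i, j] == 1:
                total += (s[i, j] - 1.0) ** 2
            else:
                total += s[i, j] ** 2
    return total / (n * n)


def cross_similarity_loop(s12: np.ndarray, s34: np.ndarray, tau: float) -> float:
    """Row-instance contrast both ways (rows of S are the instances)."""
    return ntxent_columns_loop(s12.T, s34.T, tau) + ntxent_columns_loop(s34.T, s12.T, tau)


def pairwise_distances_loop(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((x[i] - x[j]) ** 2).sum())
    return d


def dm_affinity_loop(d: np.ndarray, k_bw: int) -> np.ndarray:
    """Literal per-pair evaluation of the adaptive-bandwidth kernel."""
    n = d.shape[0]
    sigma = np.empty(n)
    for i in range(n):
        others = np.sort(np.delete(d[i], i))
        sigma[i] = others[k_bw - 1]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 0.5 * (
                np.exp(-d[i, j] / (2.0 * sigma[i] ** 2)) + np.exp(-d[i, j] / (2.0 * sigma[j] ** 2))
            )
    np.fill_diagonal(out, 1.0)
    return out


def topk_rows_loop(scores: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Full-sort per-row top-k with lower-index tie-break; self excluded."""
    n = scores.shape[0]
    directed = np.zeros((n, n))
    for i in range(n):
        pairs = [(scores[i, j], j) for j in range(n) if j != i]
        pairs.sort(key=lambda t: (-t[0] if largest else t[0], t[1]))
        for _, j in pairs[:k]:
            directed[i, j] = 1.0
    return directed


def accuracy_bruteforce(labels: np.ndarray, truth: np.ndarray) -> float:
    """Maximize matches over every one-to-one cluster <-> class assignment."""
    pred_vals = sorted(set(labels.tolist()))
    true_vals = sorted(set(truth.tolist()))
    best = 0
    if len(pred_vals) <= len(true_vals):
        for perm in itertools.permutations(true_vals, len(pred_vals)):
            mapping = dict(zip(pred_vals, perm))
            best = max(best, sum(mapping[p] == t for p, t in zip(labels, truth)))
    else:
        for perm in itertools.permutations(pred_vals, len(true_vals)):
            mapping = dict(zip(perm, true_vals))
            best = max(best, sum(mapping.get(p) == t for p, t in zip(labels, truth)))
    return best / len(labels)


def kmeans_best_2partition(points: np.ndarray) -> frozenset:
    """Exhaustive minimal within-cluster sum of squares over all 2-partitions."""
    n = len(points)
    best, best_cost = None, np.inf
    for mask in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0 to kill symmetry
        groups = ([], [])
        for i in range(n):
            groups[(mask >> i) & 1].append(i)
        if not groups[0] or not groups[1]:
            continue
        cost = 0.0
        for g in groups:
            pts = points[g]
            cost += ((pts - pts.mean(axis=0)) ** 2).sum()
        if cost < best_cost:
            best_cost = cost
            best = frozenset(frozenset(g) for g in groups)
    return best
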