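"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — enumeration, direct scans,
closed forms — and shares no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_tail_enum(universe: int, n_a: int, n_b: int, overlap: int) -> float:
    """P(|A ∩ B| >= overlap) by exact counting over draws of B."""
    total = comb(universe, n_b)
    count = 0
    for k in range(overlap, min(n_a, n_b) + 1):
        count += comb(n_a, k) * comb(universe - n_a, n_b - k)
    return count / total


def binomial_tail_enum(n_concordant: int, n_overlap: int) -> float:
    """P(X >= n_concordant), X ~ Binomial(n, 1/2), by summing the pmf."""
    if n_overlap == 0:
        return 1.0
    return sum(comb(n_overlap, k) for k in range(n_concordant, n_overlap + 1)) / 2**n_overlap


def spearman_no_ties(x: np.ndarray, y: np.ndarray) -> float:
    """1 - 6 sum d^2 / (n (n^2 - 1)); valid only without ties."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    return 1 - 6 * float(((rx - ry) ** 2).sum()) / (n * (n**2 - 1))


def profile_corr_leave_two_out(D: np.ndarray, i: int, j: int) -> float:
    """Pearson correlation of rows i, j of D over columns excluding i and j."""
    cols = [k for k in range(D.shape[0]) if k not in (i, j)]
    return float(np.corrcoef(D[i, cols], D[j, cols])[0, 1])


def ks_d_scan(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample KS D by direct ECDF evaluation at every data point."""
    pts = np.concatenate([sample_a, sample_b])
    d = 0.0
    for x in pts:
        fa = (sample_a <= x).mean()
        fb = (sample_b <= x).mean()
        d = max(d, abs(fa - fb))
    return d


def ks_d_uniform_scan(sample: np.ndarray) -> float:
    """One-sample KS D against Uniform(0,1) by scanning the sorted sample."""
    s = np.sort(sample)
    n = len(s)
    d = 0.0
    for i, x in enumerate(s):
        d = max(d, abs((i + 1) / n - x), abs(x - i / n))
    return d


def all_dendrogram_orders(Z: np.ndarray, n: int) -> list[list[int]]:
    """Every leaf order consistent with a scipy linkage matrix.

    Generated by recursively flipping each internal node's children
    (2**(n-1) orders for a binary tree of n leaves).
    """

    def orders(node: int) -> list[list[int]]:
        if node < n:
            return [[node]]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        out = []
        for lo in orders(left):
            for ro in orders(right):
                out.append(lo + ro)
                out.append(ro + lo)
        return out

    return orders(2 * n - 2)


def best_leaf_order_cost(Z: np.ndarray, dist: np.ndarray) -> float:
    """Minimum total adjacent-leaf distance over all dendrogram-consistent orders."""
    n = dist.shape[0]
    best = np.inf
    for order in all_dendrogram_orders(Z, n):
        cost = sum(dist[order[i], order[i + 1]] for i in range(n - 1))
        best = min(best, cost)
    return float(best)


def ttest_pooled(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic (y-group minus x-group)."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    return (np.mean(y) - np.mean(x)) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def exhaustive_perm_p(values: np.ndarray, member: np.ndarray) -> float:
    """Exact two-sided permutation p for the pooled t over all label splits."""
    n = len(values)
    n1 = int(member.sum())
    t_obs = abs(ttest_pooled(values[~member], values[member]))
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        m = np.zeros(n, dtype=bool)
        m[list(idx)] = True
        t = abs(ttest_pooled(values[~m], values[m]))
        count += t >= t_obs - 1e-12
        total += 1
    return count / total
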