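"""Independent brute-force oracles used to validate the exact statistics.

Everything here is deliberately naive and kept separate from the package:
probabilities come from integer factorials, enumerations are exhaustive,
and no code path is shared with the implementations under test.
"""

from __future__ import annotations

import itertools
from math import comb, factorial

import numpy as np


def table_probability(table) -> float:
    """Exact hypergeometric probability of a table given its margins."""
    table = [list(map(int, row)) for row in table]
    row_sums = [sum(r) for r in table]
    col_sums = [sum(c) for c in zip(*table)]
    n = sum(row_sums)
    num = 1
    for s in row_sums + col_sums:
        num *= factorial(s)
    den = factorial(n)
    for row in table:
        for x in row:
            den *= factorial(x)
    return num / den


def enumerate_fisher_2x2(table) -> float:
    """Two-sided Fisher p by full enumeration (point-probability rule)."""
    table = np.asarray(table, dtype=int)
    r0, r1 = table.sum(axis=1)
    c0, c1 = table.sum(axis=0)
    p_obs = table_probability(table)
    total = 0.0
    for x in range(max(0, c0 - r1), min(r0, c0) + 1):
        t = [[x, r0 - x], [c0 - x, r1 - (c0 - x)]]
        p = table_probability(t)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def enumerate_freeman_halton(table) -> float:
    """Exact r×c test by exhaustive product enumeration of candidate tables."""
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    nrow, ncol = table.shape
    p_obs = table_probability(table)
    ranges = [range(min(row_sums[i], col_sums[j]) + 1)
              for i in range(nrow - 1) for j in range(ncol - 1)]
    total = 0.0
    for cells in itertools.product(*ranges):
        t = np.zeros((nrow, ncol), dtype=int)
        t[:nrow - 1, :ncol - 1] = np.reshape(cells, (nrow - 1, ncol - 1))
        t[:nrow - 1, ncol - 1] = row_sums[:nrow - 1] - t[:nrow - 1, :ncol - 1].sum(axis=1)
        t[nrow - 1, :] = col_sums - t[:nrow - 1, :].sum(axis=0)
        if (t < 0).any():
            continue
        p = table_probability(t)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def enumerate_wilcoxon_less(diffs) -> float:
    """Exact one-sided (less) signed-rank p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs:
            count += 1
    return count / 2**n


def enumerate_sign_test_two_sided(k: int, n: int) -> float:
    """Two-sided sign-test p as 2·min(tail) from exact binomial sums."""
    lower = sum(comb(n, i) for i in range(0, k + 1)) / 2**n
    upper = sum(comb(n, i) for i in range(k, n + 1)) / 2**n
    return min(1.0, 2 * min(lower, upper))


def grid_search_loglik(counts, coarse: float = 0.01, fine: float = 0.001) -> float:
    """Best 3×3-table log-likelihood over a simplex grid of haplotype freqs.

    Two stages: a global grid at ``coarse`` resolution, then a local grid
    at ``fine`` resolution around the coarse optimum, so the result has
    the fine resolution at tractable cost.
    """
    counts = np.asarray(counts, dtype=float)

    def loglik_batch(p):
        pAB, pAb, paB, pab = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
        g = np.stack([
            pab**2, 2 * paB * pab, paB**2,
            2 * pAb * pab, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB,
            pAb**2, 2 * pAB * pAb, pAB**2,
        ], axis=1)  # order: (0,0),(0,1),(0,2),(1,0),(1,1),(1,2),(2,0),(2,1),(2,2)
        c = counts.reshape(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(g > 0, np.log(np.where(g > 0, g, 1.0)), -np.inf)
            contrib = np.where(c[None, :] > 0, c[None, :] * lg, 0.0)
        return contrib.sum(axis=1)

    def simplex_grid(step, center=None, radius=None):
        k = round(1 / step)
        pts = []
        if center is None:
            it = (
                (i, j, l) for i in range(k + 1) for j in range(k + 1 - i)
                for l in range(k + 1 - i - j)
            )
        else:
            ci, cj, cl = (round(c * k) for c in center[:3])
            r = round(radius * k)
            it = (
                (i, j, l)
                for i in range(max(0, ci - r), min(k, ci + r) + 1)
                for j in range(max(0, cj - r), min(k - i, cj + r) + 1)
                for l in range(max(0, cl - r), min(k - i - j, cl + r) + 1)
            )
        for i, j, l in it:
            pts.append((i / k, j / k, l / k, (k - i - j - l) / k))
        return np.array(pts)

    grid = simplex_grid(coarse)
    ll = loglik_batch(grid)
    best = grid[np.argmax(ll)]
    local = simplex_grid(fine, center=best, radius=2 * coarse)
    ll_local = loglik_batch(local)
    return float(max(ll.max(), ll_local.max()))
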