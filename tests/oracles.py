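"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def median_oracle(values) -> float:
    """Sort-and-middle median."""
    v = sorted(values)
    n = len(v)
    mid = n // 2
    if n % 2:
        return float(v[mid])
    return float((v[mid - 1] + v[mid]) / 2)


def mean_sd_oracle(values) -> tuple[float, float]:
    """Two-pass mean and population SD."""
    n = len(values)
    mean = sum(values) / n
    var = sum((x - mean) ** 2 for x in values) / n
    return mean, math.sqrt(var)


def best_arc_t_oracle(x: np.ndarray, minw: int) -> tuple[float, int, int]:
    """Exhaustive max two-sample |t| over all arcs [i, j) vs complement,
    using the textbook pooled-variance t-statistic."""
    n = len(x)
    best_t, best = -1.0, (0, n)
    for i in range(n):
        for j in range(i + minw, n + 1):
            k = j - i
            if n - k < minw:
                continue
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            m1, m2 = inside.mean(), outside.mean()
            ss = float(((inside - m1) ** 2).sum() + ((outside - m2) ** 2).sum())
            if ss == 0:
                ss = 1e-300
            sp2 = ss / (n - 2)
            t = abs(m1 - m2) / math.sqrt(sp2 * (1 / k + 1 / (n - k)))
            if t > best_t:
                best_t, best = t, (i, j)
    return best_t, best[0], best[1]


def cbs_oracle(
    x: np.ndarray,
    alpha: float = 0.01,
    n_permutations: int = 200,
    minw: int = 3,
    seed: int = 12345,
) -> list[int]:
    """Exhaustive-search recursive changepoint detection with a plain
    (non-sequential) permutation test; returns sorted breakpoints."""
    rng = np.random.default_rng(seed)
    breakpoints: list[int] = []

    def recurse(seg: np.ndarray, offset: int) -> None:
        n = len(seg)
        if n < 2 * minw or np.all(seg == seg[0]):
            return
        t_obs, i, j = best_arc_t_oracle(seg, minw)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(seg)
            t_p, _, _ = best_arc_t_oracle(perm, minw)
            if t_p >= t_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        if p > alpha:
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        breakpoints.extend(offset + c for c in cuts)
        edges = [0, *cuts, n]
        for lo, hi in zip(edges[:-1], edges[1:]):
            recurse(seg[lo:hi], offset + lo)

    recurse(np.asarray(x, dtype=float), 0)
    return sorted(breakpoints)


def overlap_oracle(intervals: list[tuple[str, int, int]]) -> bool:
    """True if any two (chrom, start, end) intervals overlap."""
    for (c1, s1, e1), (c2, s2, e2) in itertools.combinations(intervals, 2):
        if c1 == c2 and s1 < e2 and s2 < e1:
            return True
    return False


def pairwise_bin_oracle(vectors: np.ndarray) -> list[list[int]]:
    """Brute-force clustering of identical rows (strict equality)."""
    bins: list[list[int]] = []
    for i in range(vectors.shape[0]):
        for b in bins:
            if np.array_equal(vectors[b[0]], vectors[i]):
                b.append(i)
                break
        else:
            bins.append([i])
    return bins


def best_order_oracle(d: np.ndarray) -> list[int]:
    """Exhaustive TSP-path optimum (canonical direction) for small n."""
    n = d.shape[0]
    best, best_cost = None, float("inf")
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue
        cost = sum(d[a, b] for a, b in zip(perm[:-1], perm[1:]))
        if cost < best_cost:
            best, best_cost = list(perm), cost
    return best


def dh_dosage_oracle(g_left: int, g_right: int, r_left: float, r_right: float) -> float:
    """P(origin = P2 | flanking origins) by enumeration of the two states."""
    def trans(a, b, r):
        return r if a != b else 1 - r
    w1 = trans(g_left, 1, r_left) * trans(1, g_right, r_right)
    w0 = trans(g_left, 0, r_left) * trans(0, g_right, r_right)
    return w1 / (w0 + w1)
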