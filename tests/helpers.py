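"""Independent oracles shared by the test modules.

Everything here is deliberately naive (brute force, exhaustive enumeration)
and never calls the code paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Cophenetic join-height matrix of average-linkage clustering, O(n^3).

    Clusters are merged greedily at the smallest average inter-cluster
    distance; the join height of a merge is half that distance.  Returns the
    matrix of pairwise join heights.
    """
    n = len(d)
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = np.zeros((n, n))
    while len(clusters) > 1:
        best = (math.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = float(
                    np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                )
                if avg < best[0]:
                    best = (avg, (i, j))
        dist, (i, j) = best
        for a in clusters[i]:
            for b in clusters[j]:
                heights[a, b] = heights[b, a] = dist / 2.0
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def tree_cophenetic(root, ids: list[str]) -> np.ndarray:
    """Pairwise join heights read off a clustering tree."""
    n = len(ids)
    idx = {name: i for i, name in enumerate(ids)}
    heights = np.zeros((n, n))

    def visit(node):
        if node.is_leaf:
            return [node.name]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        heights[idx[a], idx[b]] = heights[idx[b], idx[a]] = node.height
        return [leaf for g in groups for leaf in g]

    visit(root)
    return heights


def convex_hull_2d(points: np.ndarray) -> list[int]:
    """Indices of the 2-D convex hull vertices (gift wrapping)."""
    pts = np.asarray(points, float)
    n = len(pts)
    start = min(range(n), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    cur = start
    while True:
        cand = (cur + 1) % n
        for i in range(n):
            if i == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[i] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[i] - pts[cur]) >
                             np.linalg.norm(pts[cand] - pts[cur])):
                cand = i
        if cand == start:
            break
        hull.append(cand)
        cur = cand
    return hull


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of an ordered 2-D polygon."""
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def fisher_greater_exhaustive(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for table [[a, b], [c, d]] by tail summation.

    Sums hypergeometric probabilities over all tables with a first cell
    >= *a* and the same margins, using exact log-factorials.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    ntot = row1 + row2

    def log_comb(n: int, k: int) -> float:
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = log_comb(ntot, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        y = col1 - x
        if y < 0 or y > row2:
            continue
        p += math.exp(log_comb(row1, x) + log_comb(row2, y) - denom)
    return min(1.0, p)


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment (naive reference)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
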