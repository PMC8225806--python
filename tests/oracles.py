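"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the GLCM oracle is a
double loop over pixel pairs, the rank-test oracle computes rank sums from
first principles, and the area oracle counts grid squares.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, distance: int, direction: int
) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    dr, dc = _OFFSETS[direction]
    dr *= distance
    dc *= distance
    h, w = levels.shape
    P = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask[r, c] and mask[r2, c2]:
                a, b = int(levels[r, c]), int(levels[r2, c2])
                P[a, b] += 1
                P[b, a] += 1
    return P


def kruskal_h_oracle(g1, g2) -> float:
    """Tie-corrected Kruskal-Wallis H from first-principles mid-ranks."""
    pooled = np.concatenate([np.asarray(g1, float), np.asarray(g2, float)])
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    pos = 1
    tie_sizes = []
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        mid = (pos + (pos + (j - i) - 1)) / 2.0
        ranks[order[i:j]] = mid
        tie_sizes.append(j - i)
        pos += j - i
        i = j
    n1 = len(g1)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    h = 12.0 / (n * (n + 1)) * (r1 ** 2 / n1 + r2 ** 2 / (n - n1)) - 3 * (n + 1)
    correction = 1.0 - sum(t ** 3 - t for t in tie_sizes) / (n ** 3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def anova_f_oracle(g1, g2) -> float:
    """One-way F from explicit sums of squares."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    allv = np.concatenate([g1, g2])
    grand = allv.mean()
    ssb = len(g1) * (g1.mean() - grand) ** 2 + len(g2) * (g2.mean() - grand) ** 2
    ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    df_w = len(allv) - 2
    return float(ssb / (ssw / df_w))


def grid_count_area(vertices: np.ndarray, step: float = 0.01) -> float:
    """Polygon area by counting grid-square centers inside the outline."""
    from matplotlib.path import Path

    vertices = np.asarray(vertices, float)
    xmin, ymin = vertices.min(axis=0) - step
    xmax, ymax = vertices.max(axis=0) + step
    xs = np.arange(xmin + step / 2, xmax, step)
    ys = np.arange(ymin + step / 2, ymax, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = Path(vertices).contains_points(pts)
    return float(inside.sum()) * step * step
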