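"""Independent brute-force oracles used to validate the implementation.

Deliberately naive and dependency-light: point-in-polygon by scalar ray
casting, binning by per-point floor division, Monte-Carlo areas via
matplotlib's path module (a code path the package itself never uses),
bilinear interpolation as an explicit 4-neighbour weighted sum, and the
Mann-Whitney p-value by random permutation.
"""
from __future__ import annotations

import math

import numpy as np
from matplotlib.path import Path as MplPath


def on_segment(px, py, x1, y1, x2, y2, eps=1e-9) -> bool:
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    scale = max(abs(x2 - x1), abs(y2 - y1), 1.0)
    if abs(cross) > eps * scale:
        return False
    return (min(x1, x2) - eps <= px <= max(x1, x2) + eps
            and min(y1, y2) - eps <= py <= max(y1, y2) + eps)


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Ray casting with boundary points counted as inside."""
    verts = np.asarray(vertices, dtype=float)
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if on_segment(px, py, x1, y1, x2, y2):
            return True
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_bin(xy: np.ndarray, bin_size: float, origin=(0.0, 0.0)) -> dict:
    counts: dict[tuple[int, int], int] = {}
    for x, y in xy:
        key = (math.floor((x - origin[0]) / bin_size),
               math.floor((y - origin[1]) / bin_size))
        counts[key] = counts.get(key, 0) + 1
    return counts


def mc_points_in_polygon(vertices, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the polygon, membership judged by matplotlib."""
    verts = np.asarray(vertices, dtype=float)
    path = MplPath(verts, closed=True)
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    out = []
    got = 0
    while got < n:
        cand = rng.uniform(lo, hi, size=(2 * (n - got) + 64, 2))
        keep = path.contains_points(cand)
        out.append(cand[keep])
        got += keep.sum()
    return np.vstack(out)[:n]


def mc_area(vertices, n: int, rng: np.random.Generator) -> float:
    verts = np.asarray(vertices, dtype=float)
    path = MplPath(verts, closed=True)
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n, 2))
    frac = path.contains_points(pts).mean()
    return float(frac * np.prod(hi - lo))


def bilinear(img: np.ndarray, row: float, col: float) -> float:
    r0, c0 = int(math.floor(row)), int(math.floor(col))
    r0 = min(max(r0, 0), img.shape[0] - 2) if img.shape[0] > 1 else 0
    c0 = min(max(c0, 0), img.shape[1] - 2) if img.shape[1] > 1 else 0
    dr, dc = row - r0, col - c0
    r1, c1 = min(r0 + 1, img.shape[0] - 1), min(c0 + 1, img.shape[1] - 1)
    return float(img[r0, c0] * (1 - dr) * (1 - dc)
                 + img[r1, c0] * dr * (1 - dc)
                 + img[r0, c1] * (1 - dr) * dc
                 + img[r1, c1] * dr * dc)


def mannwhitney_u(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    u = 0.0
    for xi in x:
        u += (xi > y).sum() + 0.5 * (xi == y).sum()
    return float(u)


def permutation_pvalue(x, y, alternative="greater", n_draws=10_000,
                       rng: np.random.Generator | None = None) -> float:
    rng = rng or np.random.default_rng(0)
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    pooled = np.concatenate([x, y])
    u_obs = mannwhitney_u(x, y)
    count = 0
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        u = mannwhitney_u(perm[:n], perm[n:])
        count += (u >= u_obs) if alternative == "greater" else (u <= u_obs)
    return count / n_draws
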