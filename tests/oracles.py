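"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they check: the plane oracle
is a coarse-to-fine grid search, the surface oracle is an explicit neighbor
enumeration over Python sets.
"""

from __future__ import annotations

import numpy as np

_SIX_NEIGHBORS = [
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
]


def grid_search_plane(points: np.ndarray, iters: int = 60) -> tuple[float, float, float]:
    """Coarse-to-fine grid search for (p0, px, py) minimizing vertical squared
    residuals of z = p0 + px*x + py*y. Assumes |slopes| < 1.

    The search runs on xy coordinates centred at their mean — a pure
    reparameterization that decorrelates the intercept from the slopes so the
    shrinking grid cannot lose the optimum along a ridge — and the intercept
    is mapped back at the end."""
    pts = np.asarray(points, dtype=float)
    xm, ym = pts[:, 0].mean(), pts[:, 1].mean()
    x, y, z = pts[:, 0] - xm, pts[:, 1] - ym, pts[:, 2]
    c0, pxc, pyc = float(z.mean()), 0.0, 0.0
    w0, wx, wy = float(np.ptp(z)) + 1.0, 1.0, 1.0
    for _ in range(iters):
        p0s = np.linspace(c0 - w0, c0 + w0, 11)
        pxs = np.linspace(pxc - wx, pxc + wx, 11)
        pys = np.linspace(pyc - wy, pyc + wy, 11)
        P0, PX, PY = np.meshgrid(p0s, pxs, pys, indexing="ij")
        pred = P0[..., None] + PX[..., None] * x + PY[..., None] * y
        rss = ((pred - z) ** 2).sum(axis=-1)
        i0, i1, i2 = np.unravel_index(int(rss.argmin()), rss.shape)
        c0, pxc, pyc = float(p0s[i0]), float(pxs[i1]), float(pys[i2])
        w0, wx, wy = w0 * 0.5, wx * 0.5, wy * 0.5
    return c0 - pxc * xm - pyc * ym, pxc, pyc


def brute_surface(voxel_indices: np.ndarray) -> set[tuple[int, int, int]]:
    """Voxels of the set with at least one 6-connected neighbor outside it."""
    vox = {tuple(int(v) for v in row) for row in np.asarray(voxel_indices)}
    surface = set()
    for v in vox:
        for d in _SIX_NEIGHBORS:
            if (v[0] + d[0], v[1] + d[1], v[2] + d[2]) not in vox:
                surface.add(v)
                break
    return surface


def brute_mean_radius(surface_points: np.ndarray, centroid) -> float:
    """Plain-Python mean Euclidean distance from surface points to centroid."""
    c = [float(v) for v in centroid]
    total = 0.0
    pts = np.asarray(surface_points, dtype=float)
    for p in pts:
        total += sum((float(p[i]) - c[i]) ** 2 for i in range(3)) ** 0.5
    return total / len(pts)


def digital_ball(radius: int) -> np.ndarray:
    """Integer (z, y, x) indices with squared distance <= radius² from the
    origin-translated centre (radius, radius, radius)."""
    r = int(radius)
    ax = np.arange(2 * r + 1)
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = (Z - r) ** 2 + (Y - r) ** 2 + (X - r) ** 2 <= r * r
    return np.argwhere(inside)
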