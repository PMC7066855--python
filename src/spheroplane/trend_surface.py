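"""Locally weighted (LOESS) regression surface of centroid z on (x, y).

Highlights non-planar deposition trends (e.g. a parabolic depression) that a
global plane cannot express. Defaults: span 0.5, local degree 2, tricube
weights, no robustness iterations — degree 2 being the minimal local model
that captures a parabolic depression. R² is computed at the observed
centroids only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TrendSurface:
    fitted_z: np.ndarray  # predicted z at each centroid xy, μm
    span: float
    degree: int
    r_squared: float  # NaN when undefined (constant z); see r_squared_defined
    r_squared_defined: bool


def _design(dx: np.ndarray, dy: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(dx), dx, dy]
    if degree == 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.column_stack(cols)


def loess_surface(
    centroids: np.ndarray, span: float = 0.5, degree: int = 2
) -> TrendSurface:
    """Fit a LOESS surface to ``(N, 3)`` xyz centroids and report R².

    For each centroid, the span-fraction nearest neighbors (in xy) are fit
    with a weighted polynomial of the given degree using tricube weights
    ``(1 - (d/d_max)^3)^3``, and z is predicted at that centroid.
    ``r_squared = 1 - Σ(z-ẑ)²/Σ(z-z̄)²``; constant z leaves it undefined
    (NaN, flagged). Degenerate local neighborhoods raise ``ValueError``.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"centroids must be (N, 3) xyz; got shape {pts.shape}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = pts.shape[0]
    n_coef = (degree + 1) * (degree + 2) // 2
    k = max(int(np.ceil(span * n)), n_coef + 1)
    if k > n:
        raise ValueError(
            f"need at least {n_coef + 1} points within every local neighborhood; "
            f"have {n} total at span {span}"
        )

    xy = pts[:, :2]
    z = pts[:, 2]
    fitted = np.empty(n)
    for i in range(n):
        d = np.linalg.norm(xy - xy[i], axis=1)
        neigh = np.argpartition(d, k - 1)[:k]
        dn = d[neigh]
        dmax = dn.max()
        if dmax == 0:  # all neighbors coincide with the target point
            w = np.ones_like(dn)
        else:
            w = (1.0 - np.clip(dn / dmax, 0.0, 1.0) ** 3) ** 3
        if np.count_nonzero(w) < n_coef:
            raise ValueError(f"degenerate neighborhood at point {i}: too few "
                             "non-zero weights for the local polynomial")
        dx = xy[neigh, 0] - xy[i, 0]
        dy = xy[neigh, 1] - xy[i, 1]
        X = _design(dx, dy, degree)
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        if np.linalg.matrix_rank(Xw) < n_coef:
            raise ValueError(f"degenerate neighborhood at point {i}: singular "
                             "local design matrix")
        beta, _, _, _ = np.linalg.lstsq(Xw, z[neigh] * sw, rcond=None)
        fitted[i] = beta[0]  # local polynomial evaluated at the target point

    tss = float(np.sum((z - z.mean()) ** 2))
    rss = float(np.sum((z - fitted) ** 2))
    if tss == 0.0:
        return TrendSurface(fitted, span, degree, float("nan"), False)
    return TrendSurface(fitted, span, degree, 1.0 - rss / tss, True)
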