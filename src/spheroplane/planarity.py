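"""Least-squares plane fitting and normalized centroid-to-plane distances.

The plane is parameterized as ``z = p0 + px*x + py*y`` (μm; slopes
dimensionless) and is fit by ordinary least squares on the vertical (z)
residuals, which is the only fitting criterion whose coefficients match that
functional form directly.

Per spheroid, the distance ``d_i`` from its centroid to the plane is divided
by the spheroid's mean radius ``r̄_i``; a normalized value of 0 means the
plane bisects the spheroid, while values above 1 suggest the plane misses it
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class SingularFitError(ValueError):
    """Raised when the xy configuration does not determine a unique plane."""


@dataclass(frozen=True)
class PlaneFit:
    """Coefficients of the least-squares plane ``z = p0 + px*x + py*y``."""

    p0: float  # z-intercept, μm
    px: float  # slope in x, dimensionless
    py: float  # slope in y, dimensionless
    n_points: int = 0
    rss: float = 0.0  # residual sum of squares, μm²

    def predict_z(self, x, y):
        return self.p0 + self.px * np.asarray(x) + self.py * np.asarray(y)


@dataclass(frozen=True)
class PlanarityRecord:
    """Normalized distance of one spheroid centroid to the fit plane."""

    well_id: str | None
    d: float  # μm
    r_bar: float  # μm
    normalized: float  # d / r_bar, dimensionless

    @property
    def out_of_plane(self) -> bool:
        """True when the plane likely misses the spheroid (normalized > 1)."""
        return self.normalized > 1.0


@dataclass(frozen=True)
class PlanarityReport:
    plane: PlaneFit
    records: tuple[PlanarityRecord, ...]
    mean: float
    median: float
    max: float
    distance_mode: str = "perpendicular"


def fit_plane(centroids: np.ndarray | Sequence[Sequence[float]]) -> PlaneFit:
    """Fit ``z = p0 + px*x + py*y`` to ``(N, 3)`` xyz points (μm) by OLS.

    Raises
    ------
    SingularFitError
        For fewer than 3 points or collinear/degenerate xy configurations.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"centroids must be (N, 3) xyz; got shape {pts.shape}")
    n = pts.shape[0]
    if n < 3:
        raise SingularFitError(f"need >= 3 points for a unique plane fit; got {n}")
    design = np.column_stack([np.ones(n), pts[:, 0], pts[:, 1]])
    if np.linalg.matrix_rank(design) < 3:
        raise SingularFitError("xy positions are collinear; plane fit is singular")
    coeffs, _, _, _ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    resid = pts[:, 2] - design @ coeffs
    return PlaneFit(
        p0=float(coeffs[0]),
        px=float(coeffs[1]),
        py=float(coeffs[2]),
        n_points=n,
        rss=float(resid @ resid),
    )


def point_plane_distance(
    point: Sequence[float], plane: PlaneFit, mode: str = "perpendicular"
) -> float:
    """Distance (μm) from an xyz point to the plane.

    ``mode='perpendicular'`` gives the Euclidean point-to-plane distance
    ``|z - (p0 + px*x + py*y)| / sqrt(1 + px² + py²)``; ``mode='vertical'``
    drops the normalization (pure z residual). At slope magnitudes below
    ~0.02 the two differ by < 0.02%.
    """
    x, y, z = (float(v) for v in point)
    vertical = abs(z - (plane.p0 + plane.px * x + plane.py * y))
    if mode == "vertical":
        return vertical
    if mode == "perpendicular":
        return vertical / float(np.sqrt(1.0 + plane.px**2 + plane.py**2))
    raise ValueError(f"unknown distance mode {mode!r}")


def planarity_report(spheroids: Iterable, mode: str = "perpendicular") -> PlanarityReport:
    """Fit a plane to all spheroid centroids and summarize d_i / r̄_i.

    ``spheroids`` are objects exposing ``centroid`` (xyz μm), ``mean_radius``
    (μm) and optionally ``well_id`` (e.g. ``segmentation.SpheroidObject``).
    Summary statistics (mean, median, max) run over the normalized values;
    the median of an even-sized list is the mean of the two central values.
    """
    spheroids = list(spheroids)
    centroids = np.array([s.centroid for s in spheroids], dtype=float)
    plane = fit_plane(centroids)
    records = []
    for s in spheroids:
        d = point_plane_distance(s.centroid, plane, mode=mode)
        r_bar = float(s.mean_radius)
        records.append(
            PlanarityRecord(
                well_id=getattr(s, "well_id", None),
                d=d,
                r_bar=r_bar,
                normalized=d / r_bar,
            )
        )
    normalized = np.array([r.normalized for r in records])
    return PlanarityReport(
        plane=plane,
        records=tuple(records),
        mean=float(np.mean(normalized)),
        median=float(np.median(normalized)),
        max=float(np.max(normalized)),
        distance_mode=mode,
    )


def summarize_samples(sample_means: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n−1 denominator) of
    per-sample summary values, the mean ± SD convention used for reporting."""
    vals = np.asarray(sample_means, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 values for a sample standard deviation")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))
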