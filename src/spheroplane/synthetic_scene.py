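"""Synthetic spheroid-microarray scenes and rendered confocal-style stacks.

Scenes place up to 96 ellipsoidal spheroids on an 8×12 grid. Centroid
z-positions follow a tilted plane plus optional parabolic bowing along x
(modeling a depression running parallel to the y-axis) plus Gaussian noise;
per-well Bernoulli draws decide capture. Rendering produces a voxel stack
with depth-dependent exponential attenuation of the fluorescence signal and
optional Gaussian background noise, so the whole downstream pipeline is
testable against known ground truth.

All randomness flows from a single seed; independent sub-streams are derived
per well (and per plate) so outcomes are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

from .image_io import (
    N_COLS,
    N_ROWS,
    ImageStack,
    WellPlateMap,
    index_to_well,
)
from .planarity import PlaneFit


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the spheroid-array generative model (lengths in μm)."""

    grid_rows: int = N_ROWS
    grid_cols: int = N_COLS
    pitch: float = 3800.0  # center-to-center grid spacing
    mean_diameter: float = 500.0
    diameter_cv: float = 0.0  # coefficient of variation of the diameter
    axis_ratio_range: tuple[float, float] = (1.0, 1.0)  # ellipsoid semi-axis ratios
    plane_p0: float = 500.0
    plane_px: float = 0.0
    plane_py: float = 0.0
    bowl_coeff: float = 0.0  # 1/μm; parabolic bowing along x (0 disables)
    z_noise_sd: float = 0.0
    capture_prob: float | np.ndarray = 1.0  # scalar or (grid_rows, grid_cols)
    rng_seed: int = 0
    grid_origin_x: float | None = None  # x of column 1; default pitch/2
    grid_origin_y: float | None = None  # y of row A; default pitch/2

    def __post_init__(self) -> None:
        if self.pitch <= self.mean_diameter:
            raise ValueError("pitch must exceed mean_diameter")
        if self.diameter_cv < 0 or self.z_noise_sd < 0:
            raise ValueError("diameter_cv and z_noise_sd must be >= 0")
        lo, hi = self.axis_ratio_range
        if not (0 < lo <= hi):
            raise ValueError("axis_ratio_range must be a positive interval (lo, hi)")
        p = self.capture_matrix()
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("capture_prob must lie in [0, 1] elementwise")

    def capture_matrix(self) -> np.ndarray:
        p = np.asarray(self.capture_prob, dtype=float)
        if p.ndim == 0:
            return np.full((self.grid_rows, self.grid_cols), float(p))
        if p.shape != (self.grid_rows, self.grid_cols):
            raise ValueError(
                f"capture_prob matrix must be {(self.grid_rows, self.grid_cols)}; got {p.shape}"
            )
        return p

    @property
    def origin_x(self) -> float:
        return self.pitch / 2 if self.grid_origin_x is None else self.grid_origin_x

    @property
    def origin_y(self) -> float:
        return self.pitch / 2 if self.grid_origin_y is None else self.grid_origin_y

    def node_xy(self, row: int, col: int) -> tuple[float, float]:
        """Physical xy (μm) of grid node (row, col); row A / column 1 at origin."""
        return self.origin_x + col * self.pitch, self.origin_y + row * self.pitch


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry and signal model for rendering (lengths in μm)."""

    voxel_xy: float = 10.0
    section_thickness: float = 30.0  # optical section spacing (z)
    field_x: float = 25000.0
    field_y: float = 15000.0
    field_z: float = 1000.0
    attenuation_length: float = float("inf")  # μm of tissue; inf disables
    background_noise_sd: float = 0.0
    foreground_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.voxel_xy <= 0 or self.section_thickness <= 0:
            raise ValueError("voxel sizes must be positive")
        if min(self.field_x, self.field_y, self.field_z) <= 0:
            raise ValueError("field dimensions must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Voxel grid shape (nz, ny, nx)."""
        nz = int(round(self.field_z / self.section_thickness))
        ny = int(round(self.field_y / self.voxel_xy))
        nx = int(round(self.field_x / self.voxel_xy))
        return nz, ny, nx

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.section_thickness, self.voxel_xy, self.voxel_xy)


@dataclass(frozen=True)
class TrueSpheroid:
    """Ground-truth ellipsoid: centroid xyz μm, semi-axes μm, rotation matrix."""

    well_id: str
    centroid: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def max_extent(self) -> float:
        return float(max(self.semi_axes))


@dataclass(frozen=True)
class GroundTruthScene:
    """Known spheroid positions, shapes and capture outcomes for one block."""

    spheroids: tuple[TrueSpheroid, ...]
    captured: np.ndarray  # boolean (grid_rows, grid_cols)
    true_plane: PlaneFit
    rng_seed: int
    config: SceneConfig

    def __post_init__(self) -> None:
        if int(np.sum(self.captured)) != len(self.spheroids):
            raise ValueError("captured matrix and spheroid list disagree")
        for s in self.spheroids:
            if min(s.semi_axes) <= 0:
                raise ValueError(f"non-positive semi-axis on {s.well_id}")

    @property
    def n_spheroids(self) -> int:
        return len(self.spheroids)

    def capture_map(self) -> WellPlateMap:
        if self.captured.shape != (N_ROWS, N_COLS):
            raise ValueError("capture_map requires a full 8x12 grid scene")
        return WellPlateMap(self.captured.astype(float))

    def centroids(self) -> np.ndarray:
        return np.array([s.centroid for s in self.spheroids], dtype=float)


def _well_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def generate_block_scene(
    config: SceneConfig, field_z: float | None = None
) -> GroundTruthScene:
    """Draw capture outcomes, positions and shapes for one receiver block.

    For each captured well the centroid sits at the grid node in xy, with

    ``z = p0 + px*x + py*y + bowl_coeff*(x - x_center)^2 + N(0, z_noise_sd)``

    where ``x_center`` is the grid midline, so positive ``bowl_coeff`` forms
    a depression running parallel to the y-axis. Semi-axes are
    ``mean_diameter/2`` (jittered by ``diameter_cv``) scaled per axis by
    ratios drawn from ``axis_ratio_range``; orientation is a uniform random
    rotation. Deterministic given ``config.rng_seed``.

    When ``field_z`` is given, a configuration whose spheroids would protrude
    outside ``[0, field_z]`` raises ``ValueError`` (incompatible geometry).
    """
    p = config.capture_matrix()
    rows, cols = config.grid_rows, config.grid_cols
    streams = _well_streams(config.rng_seed, rows * cols)
    x_center = config.origin_x + (cols - 1) * config.pitch / 2

    spheroids: list[TrueSpheroid] = []
    captured = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            rng = streams[r * cols + c]
            if rng.uniform() >= p[r, c]:
                continue
            captured[r, c] = True
            x, y = config.node_xy(r, c)
            z = (
                config.plane_p0
                + config.plane_px * x
                + config.plane_py * y
                + config.bowl_coeff * (x - x_center) ** 2
            )
            if config.z_noise_sd > 0:
                z += rng.normal(0.0, config.z_noise_sd)
            radius = config.mean_diameter / 2
            if config.diameter_cv > 0:
                radius *= max(rng.normal(1.0, config.diameter_cv), 0.05)
            lo, hi = config.axis_ratio_range
            ratios = rng.uniform(lo, hi, size=3)
            if lo == hi == 1.0:
                orientation = np.eye(3)
            else:
                orientation = special_ortho_group.rvs(3, random_state=rng)
            spheroids.append(
                TrueSpheroid(
                    well_id=index_to_well(r, c) if (rows, cols) == (N_ROWS, N_COLS)
                    else f"R{r + 1}C{c + 1}",
                    centroid=(float(x), float(y), float(z)),
                    semi_axes=tuple(float(radius * q) for q in ratios),
                    orientation=orientation,
                )
            )

    scene = GroundTruthScene(
        spheroids=tuple(spheroids),
        captured=captured,
        true_plane=PlaneFit(config.plane_p0, config.plane_px, config.plane_py),
        rng_seed=config.rng_seed,
        config=config,
    )
    if field_z is not None:
        _check_fit_z(scene, field_z)
    return scene


def _check_fit_z(scene: GroundTruthScene, field_z: float) -> None:
    for s in scene.spheroids:
        z = s.centroid[2]
        if z - s.max_extent < 0 or z + s.max_extent > field_z:
            raise ValueError(
                f"spheroid {s.well_id} (z={z:.1f} μm, extent {s.max_extent:.1f} μm) "
                f"protrudes outside field_z={field_z:g} μm; incompatible geometry"
            )


def render_stack(
    scene: GroundTruthScene,
    imaging: ImagingConfig,
    noise_seed: int | None = None,
) -> ImageStack:
    """Render a scene into a voxel stack.

    Inside each ellipsoid the intensity is
    ``foreground_intensity * exp(-t / attenuation_length)`` where ``t`` is the
    tissue path length from the voxel toward the objective (taken at the high-z
    face), so voxels deeper inside tissue are dimmer. Gaussian background
    noise with SD ``background_noise_sd`` is added everywhere. Deterministic
    given scene and seed (``noise_seed`` defaults to a sub-stream of the
    scene's seed).
    """
    nz, ny, nx = imaging.grid_shape
    if min(nz, ny, nx) < 1:
        raise ValueError(
            f"voxel grid empty in some axis: {(nz, ny, nx)} for fields "
            f"{(imaging.field_z, imaging.field_y, imaging.field_x)}"
        )
    _check_fit_z(scene, imaging.field_z)
    for s in scene.spheroids:
        x, y, _ = s.centroid
        if not (0 <= x <= imaging.field_x and 0 <= y <= imaging.field_y):
            raise ValueError(f"spheroid {s.well_id} centroid outside xy field")

    dz, dy, dx = imaging.spacing
    occ = np.zeros((nz, ny, nx), dtype=bool)
    for s in scene.spheroids:
        _carve_ellipsoid(occ, s, imaging)

    if np.isfinite(imaging.attenuation_length):
        # tissue voxels strictly above (closer to the objective), per xy column
        above = np.flip(np.cumsum(np.flip(occ, axis=0), axis=0), axis=0) - occ
        signal = np.where(
            occ,
            imaging.foreground_intensity
            * np.exp(-(above * dz) / imaging.attenuation_length),
            0.0,
        ).astype(np.float32)
    else:
        signal = occ.astype(np.float32) * np.float32(imaging.foreground_intensity)

    if imaging.background_noise_sd > 0:
        if noise_seed is None:
            noise_seed = np.random.SeedSequence(scene.rng_seed).spawn(1)[0]
        rng = np.random.default_rng(noise_seed)
        signal = signal + rng.normal(
            0.0, imaging.background_noise_sd, size=signal.shape
        ).astype(np.float32)

    return ImageStack(voxels=signal, spacing=(dz, dy, dx), origin=(0.0, 0.0, 0.0))


def _carve_ellipsoid(occ: np.ndarray, s: TrueSpheroid, imaging: ImagingConfig) -> None:
    """Set occupancy True for voxels whose centres fall inside the ellipsoid."""
    nz, ny, nx = occ.shape
    dz, dy, dx = imaging.spacing
    cx, cy, cz = s.centroid
    ext = s.max_extent

    # bounding index ranges (voxel centre at (i + 0.5) * spacing)
    def rng_idx(c, e, step, n):
        lo = max(int(np.floor((c - e) / step - 0.5)), 0)
        hi = min(int(np.ceil((c + e) / step + 0.5)), n - 1)
        return lo, hi

    zlo, zhi = rng_idx(cz, ext, dz, nz)
    ylo, yhi = rng_idx(cy, ext, dy, ny)
    xlo, xhi = rng_idx(cx, ext, dx, nx)
    if zlo > zhi or ylo > yhi or xlo > xhi:
        return

    zc = (np.arange(zlo, zhi + 1) + 0.5) * dz - cz
    yc = (np.arange(ylo, yhi + 1) + 0.5) * dy - cy
    xc = (np.arange(xlo, xhi + 1) + 0.5) * dx - cx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # physical offsets in xyz order
    local = pts @ s.orientation  # rotate into ellipsoid frame
    a, b, c = s.semi_axes
    inside = (local[..., 0] / a) ** 2 + (local[..., 1] / b) ** 2 + (
        local[..., 2] / c
    ) ** 2 <= 1.0
    occ[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1] |= inside


def generate_plate_series(
    n_plates: int,
    capture_prob: float | np.ndarray,
    rng_seed: int,
) -> list[WellPlateMap]:
    """Independent Bernoulli capture draws for each of ``n_plates`` plates.

    ``capture_prob`` is a scalar or an 8×12 matrix. One RNG sub-stream per
    plate, so plate k is reproducible regardless of how many plates follow.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    p = np.asarray(capture_prob, dtype=float)
    if p.ndim == 0:
        p = np.full((N_ROWS, N_COLS), float(p))
    if p.shape != (N_ROWS, N_COLS):
        raise ValueError(f"capture_prob matrix must be {(N_ROWS, N_COLS)}; got {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("capture_prob must lie in [0, 1] elementwise")
    maps = []
    for child in np.random.SeedSequence(rng_seed).spawn(n_plates):
        rng = np.random.default_rng(child)
        draws = rng.uniform(size=(N_ROWS, N_COLS)) < p
        maps.append(WellPlateMap(draws.astype(float)))
    return maps


_SCENE_COLUMNS = ["well_id", "cx_um", "cy_um", "cz_um", "a_um", "b_um", "c_um"]


def scene_to_csv(scene: GroundTruthScene, path: str | Path) -> None:
    """Serialize ground truth to CSV, one row per spheroid.

    Orientation matrices are not serialized; a scene loaded back assumes
    axis-aligned ellipsoids (sufficient for centroid/size oracles)."""
    rows = [
        [s.well_id, *s.centroid, *s.semi_axes]
        for s in scene.spheroids
    ]
    pd.DataFrame(rows, columns=_SCENE_COLUMNS).to_csv(str(path), index=False)


def scene_centroids_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    missing = set(_SCENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scene CSV missing columns: {sorted(missing)}")
    return df


def scene_with_seed(config: SceneConfig, seed: int) -> SceneConfig:
    """Convenience: copy of ``config`` with a different seed."""
    return replace(config, rng_seed=seed)
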