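"""Volumetric image stacks and 96-well plate maps.

Conventions used throughout the package:

* voxel arrays are ordered ``(z, y, x)``;
* all physical quantities are micrometres (μm);
* the physical centre of voxel index ``i`` along an axis is
  ``origin + (i + 0.5) * spacing``, with the origin at the block corner
  nearest well A1;
* ``z`` increases away from the bottom surface of the agar block;
* plate maps place well A1 at the top-left (row ``A``, column ``1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

ROW_LABELS: tuple[str, ...] = tuple("ABCDEFGH")
COL_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, 13))
N_ROWS = len(ROW_LABELS)
N_COLS = len(COL_LABELS)


@dataclass(frozen=True)
class ImageStack:
    """A 3D intensity volume with anisotropic physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array in ``(z, y, x)`` order.
    spacing
        ``(dz, dy, dx)`` voxel spacing in μm.
    origin
        ``(z0, y0, x0)`` physical position, in μm, of the corner of the
        voxel grid (well A1 side).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x); got ndim={vox.ndim}")
        if min(vox.shape) < 1:
            raise ValueError(f"every axis must have size >= 1; got shape {vox.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values; got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def physical_points(self, indices: np.ndarray) -> np.ndarray:
        """Map integer voxel indices ``(N, 3)`` in (z, y, x) order to the
        physical μm coordinates of the voxel centres."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class WellPlateMap:
    """An 8×12 plate matrix of boolean occupancy or fractional success.

    ``values[r, c]`` corresponds to well ``row_labels[r]``/``col_labels[c]``,
    with A1 at ``values[0, 0]``.
    """

    values: np.ndarray
    row_labels: tuple[str, ...] = field(default=ROW_LABELS)
    col_labels: tuple[str, ...] = field(default=COL_LABELS)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_ROWS, N_COLS):
            raise ValueError(f"plate map must be {N_ROWS}x{N_COLS}; got {vals.shape}")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("plate map values must lie in [0, 1]")
        self.values = vals
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)

    @classmethod
    def full(cls, value: float) -> "WellPlateMap":
        return cls(np.full((N_ROWS, N_COLS), float(value)))

    def as_bool(self) -> np.ndarray:
        if not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("plate map holds fractional values; not a boolean map")
        return self.values.astype(bool)

    def well_value(self, well_id: str) -> float:
        r, c = well_to_index(well_id)
        return float(self.values[r, c])


def well_to_index(well_id: str) -> tuple[int, int]:
    """``'A1'`` → ``(0, 0)``; ``'H12'`` → ``(7, 11)``."""
    row, col = well_id[0].upper(), well_id[1:]
    if row not in ROW_LABELS or col not in COL_LABELS:
        raise ValueError(f"not a 96-well id: {well_id!r}")
    return ROW_LABELS.index(row), COL_LABELS.index(col)


def index_to_well(row: int, col: int) -> str:
    return f"{ROW_LABELS[row]}{COL_LABELS[col]}"


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per z-slice."""
    tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Page ``i`` becomes z-slice ``i``; intensities are preserved without
    rescaling. ``spacing`` is ``(dz, dy, dx)`` in μm and must be supplied by
    the caller (the files written here carry no physical metadata).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"TIFF pages have inconsistent dimensions: {sorted(shapes)}")
        voxels = tif.asarray()
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis, :, :]
    return ImageStack(voxels=voxels, spacing=spacing, origin=origin)


def write_plate_map(pmap: WellPlateMap, path: str | Path) -> None:
    """Write a plate map as CSV with row labels A–H and column header 1–12.

    Boolean maps are written as integer 0/1; fractional maps keep full
    precision (``repr`` round trip)."""
    vals = pmap.values
    if np.all(np.isin(vals, (0.0, 1.0))):
        vals = vals.astype(int)
    df = pd.DataFrame(vals, index=list(pmap.row_labels), columns=list(pmap.col_labels))
    df.to_csv(str(path), index_label="row", float_format="%.17g")


def read_plate_map(path: str | Path) -> WellPlateMap:
    """Read a plate-map CSV (header 1–12, row labels A–H, values in [0, 1])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(str(path), index_col=0, float_precision="round_trip")
    rows = tuple(str(r) for r in df.index)
    cols = tuple(str(c) for c in df.columns)
    if rows != ROW_LABELS:
        raise ValueError(f"expected row labels {ROW_LABELS} in order; got {rows}")
    if cols != COL_LABELS:
        raise ValueError(f"expected column labels {COL_LABELS} in order; got {cols}")
    values = df.to_numpy(dtype=float)
    return WellPlateMap(values=values)
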