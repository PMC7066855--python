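"""Per-well, per-row and per-column capture-success statistics across plates.

The default sample unit for the row/column tests is the per-plate row
(column) mean success fraction, n = number of plates, since plates are the
independent replicates (wells within a plate share handling). A two-sided
one-sample t-test compares each row/column sample against the grand mean
success rate of the same data; significance uses strict p < alpha and no
multiple-testing correction by default (a Bonferroni option is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .image_io import COL_LABELS, ROW_LABELS, WellPlateMap


@dataclass(frozen=True)
class GroupStat:
    """One row's or column's test against the grand mean success rate."""

    label: str
    mean: float
    sem: float
    t: float  # may be +/-inf when the sample has zero variance
    p: float
    significant: bool
    n: int


@dataclass(frozen=True)
class CaptureSummary:
    per_well_mean: np.ndarray  # 8×12 fractions
    grand_mean: float
    grand_sd: float
    row_stats: tuple[GroupStat, ...]
    col_stats: tuple[GroupStat, ...]
    alpha: float
    n_plates: int


def _stack_maps(maps: Sequence[WellPlateMap]) -> np.ndarray:
    if len(maps) == 0:
        raise ValueError("need at least one plate map")
    arr = np.stack([m.values for m in maps])  # (plates, 8, 12)
    return arr


def per_well_success(maps: Sequence[WellPlateMap]) -> np.ndarray:
    """Elementwise mean success fraction across plates (8×12)."""
    return _stack_maps(maps).mean(axis=0)


def grand_summary(maps: Sequence[WellPlateMap]) -> tuple[float, float]:
    """Mean and n−1 standard deviation of the per-plate success fractions."""
    arr = _stack_maps(maps)
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 plates for a standard deviation")
    per_plate = arr.mean(axis=(1, 2))
    return float(per_plate.mean()), float(per_plate.std(ddof=1))


def one_sample_t(sample: np.ndarray, null_value: float) -> tuple[float, float]:
    """Two-sided one-sample t-test of ``sample`` against ``null_value``.

    Zero within-sample variance is handled explicitly: t = ±inf with p = 0
    when the sample mean differs from the null, t = 0 with p = 1 otherwise.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if n < 2:
        raise ValueError("need >= 2 observations for a t-test")
    if np.ptp(sample) == 0.0:  # identical observations: no within-sample variance
        if sample[0] == null_value:
            return 0.0, 1.0
        return float(np.sign(sample[0] - null_value)) * float("inf"), 0.0
    mean = sample.mean()
    s = sample.std(ddof=1)
    t = (mean - null_value) / (s / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def row_col_tests(
    maps: Sequence[WellPlateMap],
    alpha: float = 0.01,
    unit: str = "plate",
    bonferroni: bool = False,
) -> tuple[tuple[GroupStat, ...], tuple[GroupStat, ...]]:
    """Row and column one-sample t-tests against the grand mean.

    ``unit='plate'`` (default): each row/column sample is its per-plate mean
    success fraction, n = n_plates. ``unit='well'``: the sample is the
    per-well mean over plates within the row/column (n = 12 or 8).
    ``bonferroni`` divides alpha by the number of tests in each family.
    """
    arr = _stack_maps(maps)
    if arr.shape[0] < 2 and unit == "plate":
        raise ValueError("need >= 2 plates for per-plate row/column tests")
    if unit not in ("plate", "well"):
        raise ValueError(f"unknown test unit {unit!r}")
    grand = float(arr.mean())

    def stats_for(axis_means: np.ndarray, labels: Sequence[str], a: float):
        out = []
        for i, label in enumerate(labels):
            sample = axis_means[:, i]
            t, p = one_sample_t(sample, grand)
            sem = float(sample.std(ddof=1) / np.sqrt(sample.size))
            out.append(
                GroupStat(
                    label=label,
                    mean=float(sample.mean()),
                    sem=sem,
                    t=t,
                    p=p,
                    significant=p < a,
                    n=sample.size,
                )
            )
        return tuple(out)

    if unit == "plate":
        row_samples = arr.mean(axis=2)  # (plates, 8)
        col_samples = arr.mean(axis=1)  # (plates, 12)
    else:
        row_samples = arr.mean(axis=0).T[:, :]  # (12, 8): wells within each row
        col_samples = arr.mean(axis=0)  # (8, 12): wells within each column

    a_row = alpha / len(ROW_LABELS) if bonferroni else alpha
    a_col = alpha / len(COL_LABELS) if bonferroni else alpha
    return (
        stats_for(row_samples, ROW_LABELS, a_row),
        stats_for(col_samples, COL_LABELS, a_col),
    )


def summarize_capture(
    maps: Sequence[WellPlateMap],
    alpha: float = 0.01,
    unit: str = "plate",
    bonferroni: bool = False,
) -> CaptureSummary:
    """Full capture report: per-well means, grand mean ± SD, row/column tests."""
    mean, sd = grand_summary(maps)
    rows, cols = row_col_tests(maps, alpha=alpha, unit=unit, bonferroni=bonferroni)
    return CaptureSummary(
        per_well_mean=per_well_success(maps),
        grand_mean=mean,
        grand_sd=sd,
        row_stats=rows,
        col_stats=cols,
        alpha=alpha,
        n_plates=len(maps),
    )
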