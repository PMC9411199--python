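"""Longitudinal quantification of sensory-axon degradation.

After front-leg amputation at 2 days post-implantation (dpi), the axon
terminals of the leg's femoral chordotonal organ degrade in the T1
neuromere, while intact control flies only photobleach slowly. Daily
2-D projections are registered to the first day's image, the mean
fluorescence of fixed regions of interest is extracted per day, values
are normalized to 1 dpi, and intact vs. amputated groups are compared
per day with a two-sided Mann-Whitney U test (exact null for the small
group sizes used, n <= 8).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .registration import register_translation
from .waves import mann_whitney_u

__all__ = [
    "DailySeries",
    "align_series",
    "roi_mean_by_day",
    "normalize_to_first_day",
    "compare_groups_by_day",
    "fit_decay_rate",
]


@dataclass
class DailySeries:
    """Per-day 2-D projections for one fly."""

    images: np.ndarray          # (n_days, Y, X)
    days: np.ndarray            # dpi indices, strictly increasing
    fly_id: str
    group: str                  # "intact" | "amputated"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.days = np.asarray(self.days, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_days, Y, X)")
        if len(self.days) != self.images.shape[0]:
            raise ValueError("days and images length mismatch")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.group not in ("intact", "amputated"):
            raise ValueError("group must be 'intact' or 'amputated'")


def align_series(series: DailySeries) -> tuple[DailySeries, np.ndarray]:
    """Translate each day's image (subpixel) onto the first day.

    Returns the aligned series and the recovered per-day (dy, dx)
    offsets. A day whose registration is undefined (constant image) is
    flagged and left unaligned.
    """
    if series.images.shape[0] < 2:
        raise ValueError("need at least two days to align")
    ref = series.images[0]
    aligned = series.images.copy()
    offsets = np.zeros((series.images.shape[0], 2))
    for d in range(1, series.images.shape[0]):
        img = series.images[d]
        if np.ptp(img) == 0:
            warnings.warn(f"day index {d}: constant image, left unaligned")
            continue
        dy, dx = register_translation(img, ref)
        offsets[d] = (dy, dx)
        aligned[d] = ndimage.shift(img, (-dy, -dx), order=1, mode="nearest")
    return (
        DailySeries(aligned, series.days, series.fly_id, series.group),
        offsets,
    )


def roi_mean_by_day(series: DailySeries, rois: np.ndarray) -> pd.DataFrame:
    """Mean intensity per day and per ROI of a labeled mask.

    ROIs are drawn on the day-1 image and held fixed after alignment.
    Returns a table with columns (fly_id, group, day, roi_id,
    mean_fluorescence).
    """
    rois = np.asarray(rois)
    if rois.shape != series.images.shape[1:]:
        raise ValueError("ROI mask shape does not match images")
    labels = np.unique(rois)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("ROI mask contains no labels")
    rows = []
    for d_idx, day in enumerate(series.days):
        img = series.images[d_idx]
        for label in labels:
            m = rois == label
            rows.append(
                {
                    "fly_id": series.fly_id,
                    "group": series.group,
                    "day": int(day),
                    "roi_id": int(label),
                    "mean_fluorescence": float(img[m].mean()),
                }
            )
    return pd.DataFrame(rows)


def normalize_to_first_day(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each (fly, roi) series by its first-day mean fluorescence.

    Adds a ``normalized`` column; the first day is exactly 1 and the
    transform is invariant to rescaling a fly's whole series.
    """
    out = table.copy()
    out["normalized"] = np.nan
    for (fly, roi), idx in out.groupby(["fly_id", "roi_id"]).groups.items():
        sub = out.loc[idx].sort_values("day")
        first = sub.iloc[0]["mean_fluorescence"]
        if first <= 0:
            raise ValueError(f"non-positive first-day mean for fly {fly}, roi {roi}")
        out.loc[idx, "normalized"] = out.loc[idx, "mean_fluorescence"] / first
    return out


def compare_groups_by_day(table: pd.DataFrame, roi_id: int | None = None) -> pd.Series:
    """Two-sided Mann-Whitney p-value per day, intact vs. amputated.

    Uses the exact permutation null (group sizes here are <= 8). Days
    missing either group are skipped with a warning.
    """
    tab = table if roi_id is None else table[table["roi_id"] == roi_id]
    pvals = {}
    for day, sub in tab.groupby("day"):
        intact = sub.loc[sub["group"] == "intact", "normalized"].to_numpy()
        amput = sub.loc[sub["group"] == "amputated", "normalized"].to_numpy()
        if intact.size == 0 or amput.size == 0:
            warnings.warn(f"day {day}: one group missing, skipped")
            continue
        method = "exact" if max(intact.size, amput.size) <= 8 else "normal_cc"
        pvals[int(day)] = mann_whitney_u(intact, amput, sides="two", method=method)
    return pd.Series(pvals, name="p_value").sort_index()


def fit_decay_rate(
    table: pd.DataFrame, fly_id: str, roi_id: int, start_day: int = 2
) -> float:
    """Exponential decay rate (1/day) from a log-linear fit of normalized
    fluorescence from ``start_day`` onward."""
    sub = table[(table["fly_id"] == fly_id) & (table["roi_id"] == roi_id)]
    sub = sub[sub["day"] >= start_day].sort_values("day")
    if len(sub) < 2:
        raise ValueError("need at least two days to fit a decay rate")
    days = sub["day"].to_numpy(dtype=float)
    vals = sub["normalized"].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("non-positive normalized values; cannot log-fit")
    slope, _ = np.polyfit(days, np.log(vals), 1)
    return float(-slope)
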