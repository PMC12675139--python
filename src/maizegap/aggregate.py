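"""Ensemble and spatial post-processing: medians, masks, classes, summaries.

Per-cell fields arrive as arrays with an ensemble-member axis; the ensemble
statistic is the median (robust for a five-member ensemble).  Cells enter the
analysis only if every member completed the crop cycle in at least
``min_years`` years of the period, and change maps are computed on the
crossmasked (baseline AND future) cell set.  Suitability classes and crop
failures use the 4 and 7 ton/ha yield thresholds.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "ensemble_median",
    "inclusion_mask",
    "crossmask",
    "relative_change_field",
    "classify_suitability",
    "count_failures",
    "domain_summary",
    "grid_to_dataset",
]

SUITABILITY_CLASSES = ("unsuitable", "suitable", "profitable")
UNSUITABLE_BELOW = 4.0  # ton/ha
PROFITABLE_ABOVE = 7.0  # ton/ha
FAILURE_THRESHOLD = 4.0  # ton/ha


def ensemble_median(values, axis: int = 0) -> np.ndarray:
    """Element-wise median across ensemble members.

    Even member counts average the two central order statistics.  NaNs
    (e.g. masked cells) propagate.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape[axis] < 1:
        raise ValueError("need at least one ensemble member")
    return np.median(arr, axis=axis)


def inclusion_mask(completion_flags, min_years: int = 5) -> np.ndarray:
    """Cells where every member completed the cycle in at least ``min_years`` years.

    ``completion_flags`` has shape (members, years, *cells) and is boolean;
    the boundary is inclusive (exactly ``min_years`` complete years passes).
    """
    flags = np.asarray(completion_flags, dtype=bool)
    if flags.ndim < 2:
        raise ValueError("completion_flags must have (members, years, ...) axes")
    counts = flags.sum(axis=1)  # (members, *cells)
    return np.all(counts >= min_years, axis=0)


def crossmask(baseline_mask, future_mask) -> np.ndarray:
    """Logical AND of baseline and future inclusion masks (same cell sets)."""
    a = np.asarray(baseline_mask, dtype=bool)
    b = np.asarray(future_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks cover different cell sets")
    return a & b


def relative_change_field(baseline, future, mask=None) -> np.ndarray:
    """(future - baseline)/baseline*100 per cell; NaN where baseline is 0 or masked out."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(future, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and future fields differ in shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b != 0.0, (f - b) / b * 100.0, np.nan)
    if mask is not None:
        out = np.where(np.asarray(mask, dtype=bool), out, np.nan)
    return out


def classify_suitability(
    mean_ya,
    unsuitable_below: float = UNSUITABLE_BELOW,
    profitable_above: float = PROFITABLE_ABOVE,
):
    """Suitability class from mean actual yield [ton/ha].

    Strictly below the lower threshold is "unsuitable", strictly above the
    upper one "profitable"; boundary values are plain "suitable".
    Vectorises; scalars return a string.
    """
    arr = np.asarray(mean_ya, dtype=float)
    idx = np.where(arr < unsuitable_below, 0, np.where(arr > profitable_above, 2, 1))
    if arr.ndim == 0:
        return SUITABILITY_CLASSES[int(idx)]
    return np.array(SUITABILITY_CLASSES, dtype=object)[idx]


def count_failures(
    yearly_ya,
    complete=None,
    threshold: float = FAILURE_THRESHOLD,
    count_incomplete: bool = True,
) -> int:
    """Number of crop-failure years: actual yield strictly below the threshold.

    Years with an incomplete cycle (no harvestable grain) count as failures by
    default; set ``count_incomplete`` False to score only completed seasons.
    """
    y = np.asarray(yearly_ya, dtype=float)
    if complete is None:
        return int(np.sum(y < threshold))
    c = np.asarray(complete, dtype=bool)
    if c.shape != y.shape:
        raise ValueError("yield and completion arrays differ in shape")
    fails = np.sum(c & (y < threshold))
    if count_incomplete:
        fails += np.sum(~c)
    return int(fails)


def domain_summary(values, mask=None, exclude_below: float | None = None) -> dict:
    """Spatial mean/median/quartiles over masked cells.

    ``exclude_below`` drops cells whose value is below the cutoff (used to
    focus on the viable production area).  Percentiles use linear
    interpolation between order statistics.  Raises if nothing survives.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if mask is not None:
        arr = arr[np.asarray(mask, dtype=bool).ravel()]
    arr = arr[np.isfinite(arr)]
    if exclude_below is not None:
        arr = arr[arr >= exclude_below]
    if arr.size == 0:
        raise ValueError("no cells remain after masking/exclusion")
    return {
        "mean": float(np.mean(arr)),
        "median": float(np.median(arr)),
        "p25": float(np.percentile(arr, 25)),
        "p75": float(np.percentile(arr, 75)),
        "n": int(arr.size),
    }


def grid_to_dataset(
    lats, lons, fields: dict[str, np.ndarray], attrs: dict | None = None
) -> xr.Dataset:
    """Pack per-cell fields shaped (lat, lon) into a CF-style xarray Dataset."""
    data = {
        name: (("lat", "lon"), np.asarray(values)) for name, values in fields.items()
    }
    ds = xr.Dataset(
        data,
        coords={
            "lat": ("lat", np.asarray(lats), {"units": "degrees_north"}),
            "lon": ("lon", np.asarray(lons), {"units": "degrees_east"}),
        },
        attrs=attrs or {},
    )
    return ds
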