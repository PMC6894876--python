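"""Temporal trend statistics for annual SOCD series and rasters.

For a series indexed by serial year number ``i = 1..n`` three trend
measures are computed:

* the closed-form least-squares slope
  ``(n*sum(i*x_i) - sum(i)*sum(x_i)) / (n*sum(i^2) - sum(i)^2)``;
* the Mann-Kendall sign statistic ``S`` with tie-corrected variance and
  the continuity-corrected normal deviate ``Z`` (three-way significance
  at |Z| vs 1.96);
* the Sen (Kendall) slope ``beta`` = median of all pairwise slopes.

Slopes are binned into five magnitude classes with half-open boundaries
at -0.1, -0.01, 0.01 and 0.1.  The class labels are slope-magnitude
classes and are reported independently of Mann-Kendall significance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ndvi import CLASS_NAMES, MEADOW, STEPPE
from .raster import Grid

__all__ = [
    "CLASS_LABELS", "NODATA_CLASS",
    "AnnualSeries", "TrendResult", "TrendRasterResult",
    "ols_slope", "mann_kendall", "sen_beta", "classify_trend",
    "trend_raster", "regional_series", "class_area_table",
]

Z_CRITICAL = 1.96

#: slope-magnitude classes, index = class code used in rasters
CLASS_LABELS = (
    "significant_decrease",        # slope < -0.1
    "non_significant_decrease",    # -0.1 <= slope < -0.01
    "nearly_unchangeable",         # -0.01 <= slope < 0.01
    "non_significant_increase",    # 0.01 <= slope < 0.1
    "significant_increase",        # slope >= 0.1
)
_CLASS_EDGES = (-0.1, -0.01, 0.01, 0.1)
NODATA_CLASS = -1


@dataclass
class AnnualSeries:
    """SOCD values indexed by serial year number 1..n (NaN = missing)."""

    values: np.ndarray
    start_year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("series must be 1-D")

    @property
    def n(self) -> int:
        return self.values.size

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """(serial year numbers, values) of the non-missing entries."""
        i = np.arange(1, self.n + 1, dtype=float)
        ok = np.isfinite(self.values)
        return i[ok], self.values[ok]


@dataclass
class TrendResult:
    slope: float
    mk_s: int
    mk_z: float
    sen_beta: float
    class_label: str | None
    significance: str              # "sig_increase" | "none" | "sig_decrease"


def _as_series(series) -> AnnualSeries:
    return series if isinstance(series, AnnualSeries) else AnnualSeries(np.asarray(series))


def ols_slope(series) -> float:
    """Least-squares slope on (i, x_i); NaN for degenerate input.

    Missing entries are dropped; at least two distinct time points are
    required.
    """
    i, x = _as_series(series).valid()
    n = i.size
    if n < 2:
        return np.nan
    denom = n * np.sum(i * i) - np.sum(i) ** 2
    if denom == 0:
        return np.nan
    return float((n * np.sum(i * x) - np.sum(i) * np.sum(x)) / denom)


def _mk_s_and_var(x: np.ndarray) -> tuple[int, float]:
    """Mann-Kendall S and tie-corrected Var(S) for a clean series."""
    n = x.size
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())
    var = n * (n - 1) * (2 * n + 5) / 18.0
    _, counts = np.unique(x, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5) / 18.0
    return s, var


def mann_kendall(series) -> tuple[int, float, str]:
    """(S, Z, significance) of the Mann-Kendall monotone-trend test.

    Z uses the continuity correction: (S-1)/sd for S > 0, 0 for S = 0,
    (S+1)/sd for S < 0.  Significance is the three-way rule at 1.96.
    Raises ``ValueError`` with fewer than 3 non-missing values.
    """
    _, x = _as_series(series).valid()
    if x.size < 3:
        raise ValueError("Mann-Kendall test needs at least 3 non-missing values")
    s, var = _mk_s_and_var(x)
    if var <= 0:           # all values tied
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    if z > Z_CRITICAL:
        significance = "sig_increase"
    elif z < -Z_CRITICAL:
        significance = "sig_decrease"
    else:
        significance = "none"
    return s, float(z), significance


def sen_beta(series) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(j - i), i < j."""
    i, x = _as_series(series).valid()
    n = i.size
    if n < 2:
        return np.nan
    ii, jj = np.triu_indices(n, k=1)
    slopes = (x[jj] - x[ii]) / (i[jj] - i[ii])
    return float(np.median(slopes))


def classify_trend(slope):
    """Five-level slope-magnitude class; half-open boundaries as printed.

    Scalar NaN passes through as ``None``; array input returns integer
    class codes with ``NODATA_CLASS`` for NaN.
    """
    arr = np.asarray(slope, dtype=float)
    codes = np.full(arr.shape, NODATA_CLASS, dtype=np.int8)
    ok = np.isfinite(arr)
    codes[ok & (arr < -0.1)] = 0
    codes[ok & (arr >= -0.1) & (arr < -0.01)] = 1
    codes[ok & (arr >= -0.01) & (arr < 0.01)] = 2
    codes[ok & (arr >= 0.01) & (arr < 0.1)] = 3
    codes[ok & (arr >= 0.1)] = 4
    if np.ndim(slope) == 0:
        code = int(codes[()])
        return CLASS_LABELS[code] if code != NODATA_CLASS else None
    return codes


@dataclass
class TrendRasterResult:
    slope: Grid
    mk_s: Grid
    mk_z: Grid
    sen: Grid
    classes: Grid                  # int8 codes into CLASS_LABELS, -1 nodata
    class_areas: pd.DataFrame


def trend_raster(stack: np.ndarray, mask: Grid | None = None,
                 template: Grid | None = None,
                 min_valid_years: int = 3) -> TrendRasterResult:
    """Per-pixel trend statistics over an annual stack (years, rows, cols).

    Pixels with fewer than ``min_valid_years`` non-missing years (or
    outside the steppe/meadow mask) are nodata and excluded from the
    class-area percentages.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (year, row, col)")
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 annual maps")
    nrows, ncols = stack.shape[1:]
    if template is None:
        template = mask if mask is not None else Grid(np.full((nrows, ncols), np.nan))
    if template.shape != (nrows, ncols):
        raise ValueError("template/mask georeferencing mismatch with stack")
    if mask is not None and mask.shape != (nrows, ncols):
        raise ValueError("mask shape mismatch with stack")

    slope = np.full((nrows, ncols), np.nan)
    s_arr = np.full((nrows, ncols), np.nan)
    z_arr = np.full((nrows, ncols), np.nan)
    beta = np.full((nrows, ncols), np.nan)

    in_mask = np.ones((nrows, ncols), dtype=bool)
    if mask is not None:
        in_mask = np.isin(np.asarray(mask.data), (STEPPE, MEADOW))

    for r, c in itertools.product(range(nrows), range(ncols)):
        if not in_mask[r, c]:
            continue
        series = AnnualSeries(stack[:, r, c])
        _, x = series.valid()
        if x.size < min_valid_years:
            continue
        slope[r, c] = ols_slope(series)
        s, z, _ = mann_kendall(series)
        s_arr[r, c], z_arr[r, c] = s, z
        beta[r, c] = sen_beta(series)

    codes = classify_trend(slope)
    class_grid = template.with_data(codes)
    areas = class_area_table(class_grid, mask)
    return TrendRasterResult(
        slope=template.with_data(slope),
        mk_s=template.with_data(s_arr),
        mk_z=template.with_data(z_arr),
        sen=template.with_data(beta),
        classes=class_grid,
        class_areas=areas,
    )


def class_area_table(classes: Grid, mask: Grid | None = None) -> pd.DataFrame:
    """Percentage of valid pixels in each slope class, by grassland type.

    Columns are per-type percentages plus a ``total`` column; each
    column sums to 100 over the five classes (empty strata are NaN).
    """
    codes = np.asarray(classes.data)
    strata: dict[str, np.ndarray] = {}
    if mask is not None:
        mask_codes = np.asarray(mask.data)
        for code in (STEPPE, MEADOW):
            strata[CLASS_NAMES[code]] = mask_codes == code
        strata["total"] = np.isin(mask_codes, (STEPPE, MEADOW))
    else:
        strata["total"] = np.ones(codes.shape, dtype=bool)

    out: dict[str, list[float]] = {"class": list(CLASS_LABELS)}
    for name, sel in strata.items():
        valid = sel & (codes != NODATA_CLASS)
        n = int(valid.sum())
        if n == 0:
            out[name] = [np.nan] * len(CLASS_LABELS)
        else:
            out[name] = [100.0 * float(((codes == k) & valid).sum()) / n
                         for k in range(len(CLASS_LABELS))]
    return pd.DataFrame(out)


def regional_series(stack: np.ndarray, mask: Grid, class_code: int) -> AnnualSeries:
    """Per-year mean SOCD over the pixels of one grassland type."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (year, row, col)")
    sel = np.asarray(mask.data) == class_code
    if not sel.any():
        raise ValueError(f"empty stratum: no pixels of class {class_code}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(stack[:, sel], axis=1)
    return AnnualSeries(means)
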