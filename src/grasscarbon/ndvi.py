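"""Annual NDVI compositing, block aggregation and NDVI -> SOCD mapping.

The grassland-type-specific affine transfer functions are

    steppe:  SOCD = 20.201 * NDVI - 0.9206
    meadow:  SOCD = 17.846 * NDVI + 0.0155

for the 0-30 cm layer, in kg C m^-2.  NDVI >= 0.8 is flagged as
optically saturated (flag only, no value adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import Grid

__all__ = [
    "OTHER", "STEPPE", "MEADOW", "CLASS_NAMES", "CLASS_CODES",
    "NDVIStack", "SOCDMap",
    "mvc_annual", "aggregate_blocks", "ndvi_to_socd",
    "STEPPE_COEF", "MEADOW_COEF", "SATURATION_THRESHOLD",
]

# grassland mask codes
OTHER, STEPPE, MEADOW = 0, 1, 2
CLASS_NAMES = {OTHER: "other", STEPPE: "steppe", MEADOW: "meadow"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

STEPPE_COEF = (20.201, -0.9206)    # (gain, offset)
MEADOW_COEF = (17.846, 0.0155)
SATURATION_THRESHOLD = 0.8


@dataclass
class NDVIStack:
    """Year-indexed stack of co-registered NDVI grids (NaN = nodata)."""

    years: tuple[int, ...]
    data: np.ndarray                 # (n_years, rows, cols)
    cell_size: float = 1.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (year, row, col)")
        if len(self.years) != self.data.shape[0]:
            raise ValueError("years and data length disagree")
        if any(b > a for a, b in zip(self.years[1:], self.years)):
            raise ValueError("years must be ordered")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("NDVI values must lie in [-1, 1] or be nodata")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def grid(self, year: int) -> Grid:
        idx = self.years.index(int(year))
        return Grid(self.data[idx], self.cell_size, self.x_origin, self.y_origin)

    def template(self) -> Grid:
        return Grid(np.full(self.data.shape[1:], np.nan),
                    self.cell_size, self.x_origin, self.y_origin)


@dataclass
class SOCDMap:
    """A SOCD surface plus per-pixel quality flags."""

    grid: Grid
    saturated: np.ndarray            # bool: NDVI >= saturation threshold
    clamped: np.ndarray              # bool: negative prediction set to 0
    method: str = "ndvi"
    year: int | None = None


def mvc_annual(composites) -> np.ndarray:
    """Maximum-value composite: per-pixel max ignoring nodata.

    A pixel is nodata in the output only when it is nodata in every
    input composite.
    """
    arrays = [np.asarray(c, dtype=float) for c in composites]
    if not arrays:
        raise ValueError("need at least one composite")
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"composite shape mismatch: {a.shape} vs {shape}")
    stacked = np.stack(arrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmax(stacked, axis=0)


def aggregate_blocks(grid: Grid, factor: int) -> Grid:
    """Non-overlapping factor x factor block mean, nodata-aware.

    Partial edge blocks are averaged over the cells that exist; a block
    is nodata only when all of its cells are.  Output cell size grows by
    ``factor``; the top-left corner is preserved.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    data = np.asarray(grid.data, dtype=float)
    nrows, ncols = data.shape
    pr = (-nrows) % factor
    pc = (-ncols) % factor
    padded = np.pad(data, ((0, pr), (0, pc)), constant_values=np.nan)
    blocks = padded.reshape(padded.shape[0] // factor, factor,
                            padded.shape[1] // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(blocks, axis=(1, 3))
    return Grid(out, cell_size=grid.cell_size * factor,
                x_origin=grid.x_origin, y_origin=grid.y_origin)


def ndvi_to_socd(ndvi: Grid, mask: Grid, clamp_negative: bool = True,
                 year: int | None = None) -> SOCDMap:
    """Map NDVI to 0-30 cm SOCD per grassland type.

    Steppe and meadow pixels use their own affine equations; pixels of
    any other class become nodata.  Negative predictions are clamped to
    0 (flagged) when ``clamp_negative``; NDVI at or above 0.8 raises the
    saturation flag.
    """
    ndvi.require_same_georef(mask, "grassland mask")
    vals = np.asarray(ndvi.data, dtype=float)
    codes = np.asarray(mask.data)
    socd = np.full(vals.shape, np.nan)

    for code, (gain, offset) in ((STEPPE, STEPPE_COEF), (MEADOW, MEADOW_COEF)):
        sel = (codes == code) & np.isfinite(vals)
        socd[sel] = gain * vals[sel] + offset

    saturated = np.isfinite(vals) & (vals >= SATURATION_THRESHOLD) \
        & np.isin(codes, (STEPPE, MEADOW))
    clamped = np.zeros(vals.shape, dtype=bool)
    negative = np.isfinite(socd) & (socd < 0)
    if clamp_negative:
        socd[negative] = 0.0
        clamped = negative
    return SOCDMap(grid=ndvi.with_data(socd), saturated=saturated,
                   clamped=clamped, method="ndvi", year=year)
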