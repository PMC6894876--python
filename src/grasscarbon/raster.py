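"""Minimal in-memory grid container and plain-text (ESRI ASCII) raster I/O.

Grids are row-major 2-D numpy arrays with the origin at the top-left
corner and cell-centre coordinate convention.  Nodata is carried as NaN
in float grids; categorical grids use integer codes and an explicit
nodata code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]

_GEOREF_TOL = 1e-9


@dataclass
class Grid:
    """A georeferenced 2-D grid.

    Attributes
    ----------
    data : ndarray
        2-D array, row 0 at the *top* of the map.
    cell_size : float
        Edge length of a square cell in map units.
    x_origin, y_origin : float
        Map coordinates of the top-left corner of the top-left cell.
    """

    data: np.ndarray
    cell_size: float = 1.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"grid data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= _GEOREF_TOL
            and abs(self.x_origin - other.x_origin) <= _GEOREF_TOL
            and abs(self.y_origin - other.y_origin) <= _GEOREF_TOL
        )

    def require_same_georef(self, other: "Grid", what: str = "grid") -> None:
        if not self.same_georef(other):
            raise ValueError(
                f"{what} is not co-registered: shape/georeferencing mismatch "
                f"({self.shape}, cell {self.cell_size} vs {other.shape}, cell {other.cell_size})"
            )

    def with_data(self, data: np.ndarray) -> "Grid":
        return replace(self, data=data)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell centre, each shaped like data."""
        nrows, ncols = self.shape
        xs = self.x_origin + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = -9999.0,
                     fmt: str = "%.10g") -> None:
    """Write a grid as an ESRI ASCII raster (plain text, portable)."""
    nrows, ncols = grid.shape
    data = np.asarray(grid.data, dtype=float)
    out = np.where(np.isnan(data), nodata, data)
    yll = grid.y_origin - nrows * grid.cell_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.x_origin:.10g}\n"
        f"yllcorner {yll:.10g}\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path, dtype=float) -> Grid:
    """Read an ESRI ASCII raster; nodata becomes NaN (float) or stays coded (int)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"ASCII grid shape {data.shape} disagrees with header "
                         f"({nrows}, {ncols})")
    nodata = header.get("nodata_value")
    if np.issubdtype(np.dtype(dtype), np.floating):
        if nodata is not None:
            data = np.where(data == nodata, np.nan, data)
        data = data.astype(dtype)
    else:
        data = data.astype(dtype)
    cell = header["cellsize"]
    return Grid(
        data=data,
        cell_size=cell,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
    )
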