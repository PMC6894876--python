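"""Regional SOC storage accounting and point-to-raster interpolation.

Storage per grassland type is the exact sum of per-pixel SOCD
(kg C m^-2) times cell area (m^2) over that type's valid pixels,
reported in units of 1e10 kg.  Point-based SOCD (profile methods) is
first spread to a grid by inverse-distance weighting or ordinary
kriging; both interpolators honour the data exactly at sample sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ndvi import CLASS_NAMES, MEADOW, STEPPE
from .raster import Grid

__all__ = [
    "STORAGE_UNIT_KG",
    "interpolate_points",
    "zonal_storage",
    "storage_table",
    "profile_method_storage",
]

STORAGE_UNIT_KG = 1e10          # reporting unit for storage columns


def _fit_exponential_variogram(xy: np.ndarray, values: np.ndarray,
                               n_bins: int = 10) -> tuple[float, float] | None:
    """Method-of-moments (sill, range) for gamma(h) = sill*(1-exp(-h/range)).

    Returns None when the cloud is degenerate (too few pairs or zero
    variance), signalling an IDW fallback.
    """
    n = len(values)
    if n < 4:
        return None
    ii, jj = np.triu_indices(n, k=1)
    h = np.hypot(*(xy[ii] - xy[jj]).T)
    g = 0.5 * (values[ii] - values[jj]) ** 2
    if h.max() == 0 or np.allclose(g, 0):
        return None
    edges = np.linspace(0, h.max(), n_bins + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    sill = float(np.var(values))
    if sill == 0:
        return None
    # effective range: first bin where the empirical semivariance reaches
    # ~95% of the sill, method-of-moments style
    rng = None
    for b in range(n_bins):
        sel = which == b
        if sel.any() and g[sel].mean() >= 0.95 * sill:
            rng = float(edges[b + 1]) / 3.0
            break
    if rng is None or rng <= 0:
        rng = float(h.max()) / 3.0
    return sill, rng


def _idw(xy: np.ndarray, values: np.ndarray, targets: np.ndarray,
         power: float, k: int) -> np.ndarray:
    from scipy.spatial import cKDTree

    k = min(k, len(values))
    tree = cKDTree(xy)
    dist, idx = tree.query(targets, k=k)
    dist = np.atleast_2d(dist.T).T
    idx = np.atleast_2d(idx.T).T
    out = np.empty(len(targets))
    exact = dist[:, 0] < 1e-12
    out[exact] = values[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = dist[rest] ** (-power)
        out[rest] = (w * values[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def _ordinary_kriging(xy: np.ndarray, values: np.ndarray, targets: np.ndarray,
                      sill: float, vrange: float) -> np.ndarray:
    def gamma(h):
        return sill * (1.0 - np.exp(-h / vrange))

    n = len(values)
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    k_mat = np.empty((n + 1, n + 1))
    k_mat[:n, :n] = gamma(d)
    k_mat[n, :] = 1.0
    k_mat[:, n] = 1.0
    k_mat[n, n] = 0.0
    d_t = np.hypot(targets[:, None, 0] - xy[None, :, 0],
                   targets[:, None, 1] - xy[None, :, 1])
    rhs = np.empty((len(targets), n + 1))
    rhs[:, :n] = gamma(d_t)
    rhs[:, n] = 1.0
    weights = np.linalg.solve(k_mat, rhs.T).T[:, :n]
    return weights @ values


def interpolate_points(points, template: Grid, method: str = "idw",
                       power: float = 2.0, k: int = 12,
                       variogram: tuple[float, float] | None = None) -> Grid:
    """Interpolate (x, y, value) samples onto a grid template.

    Parameters
    ----------
    points : array_like or DataFrame
        n x 3 array of (x, y, value), or a frame with x/y/value columns.
    method : {"idw", "ordinary_kriging"}
        IDW uses ``power`` (default 2) and the ``k`` (default 12)
        nearest samples.  Ordinary kriging uses an isotropic exponential
        variogram, ``variogram = (sill, range)`` or fitted by
        method-of-moments; a degenerate variogram falls back to IDW with
        a warning.  Both are exact at sample sites.
    """
    if isinstance(points, pd.DataFrame):
        pts = points[["x", "y", "value"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("points must be a non-empty n x 3 (x, y, value) array")
    xy, values = pts[:, :2], pts[:, 2]
    xs, ys = template.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])

    if method == "ordinary_kriging":
        vg = variogram if variogram is not None else _fit_exponential_variogram(xy, values)
        if vg is None:
            warnings.warn("degenerate variogram; falling back to IDW",
                          stacklevel=2)
            method = "idw"
        else:
            try:
                out = _ordinary_kriging(xy, values, targets, *vg)
            except np.linalg.LinAlgError:
                warnings.warn("singular kriging system; falling back to IDW",
                              stacklevel=2)
                method = "idw"
    if method == "idw":
        out = _idw(xy, values, targets, power, k)
    elif method != "ordinary_kriging":
        raise ValueError(f"unknown interpolation method {method!r}")
    return template.with_data(out.reshape(template.shape))


def zonal_storage(socd: Grid, mask: Grid, cell_area: float | str = "auto",
                  method: str = "", layer: str = "total") -> pd.DataFrame:
    """SOC storage by grassland type from a SOCD surface.

    ``cell_area`` is the per-pixel area in m^2, or ``"auto"`` to use the
    squared grid cell size (projected map units assumed).  Nodata pixels
    contribute to neither storage nor area.  Returns one row per type
    with storage in 1e10 kg, area in km^2 and the mean SOCD.
    """
    socd.require_same_georef(mask, "grassland mask")
    if cell_area == "auto":
        cell_area = float(socd.cell_size) ** 2
    cell_area = float(cell_area)
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")

    vals = np.asarray(socd.data, dtype=float)
    codes = np.asarray(mask.data)
    rows = []
    for code in (STEPPE, MEADOW):
        sel = (codes == code) & np.isfinite(vals)
        n = int(sel.sum())
        storage_kg = float(vals[sel].sum()) * cell_area
        rows.append({
            "method": method,
            "grassland_type": CLASS_NAMES[code],
            "layer": layer,
            "storage_1e10_kg": storage_kg / STORAGE_UNIT_KG,
            "area_km2": n * cell_area / 1e6,
            "mean_socd_kg_m2": float(vals[sel].mean()) if n else np.nan,
            "n_pixels": n,
            "present": n > 0,
        })
    return pd.DataFrame(rows)


def profile_method_storage(mean_socd: pd.DataFrame, area_km2: dict[str, float],
                           method: str = "") -> pd.DataFrame:
    """Storage rows from profile-based group means.

    ``mean_socd`` is the output of :func:`grasscarbon.profiles.group_means`
    (columns grassland_type, layer, mean_socd); ``area_km2`` maps each
    grassland type to its area.  Layer rows and the total row inherit
    the same area, so layer storages sum to the total by construction.
    """
    rows = []
    for _, rec in mean_socd.iterrows():
        gtype = rec["grassland_type"]
        if gtype not in area_km2:
            continue
        area_m2 = float(area_km2[gtype]) * 1e6
        rows.append({
            "method": method or rec.get("method", ""),
            "grassland_type": gtype,
            "layer": rec["layer"],
            "storage_1e10_kg": rec["mean_socd"] * area_m2 / STORAGE_UNIT_KG,
            "area_km2": float(area_km2[gtype]),
            "mean_socd_kg_m2": rec["mean_socd"],
        })
    return pd.DataFrame(rows)


def storage_table(summaries) -> pd.DataFrame:
    """Long-format comparison table method x grassland type x layer.

    Accepts any number of per-method summary frames (zonal or
    profile-based) and concatenates them with a stable column order;
    raster (NDVI) methods carry total-only rows, profile methods carry
    per-layer rows plus a total.
    """
    frames = [s for s in summaries if s is not None and len(s)]
    if not frames:
        raise ValueError("need at least one summary")
    cols = ["method", "grassland_type", "layer", "storage_1e10_kg",
            "area_km2", "mean_socd_kg_m2"]
    out = pd.concat(frames, ignore_index=True)
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]
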