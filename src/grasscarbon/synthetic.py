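"""Synthetic inputs with known ground truth for every pipeline stage.

All generators are driven by a single root seed; each draws from its own
derived substream (``SeedSequence([seed, stream_id])``) so any one input
can be regenerated independently and bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import pedotransfer
from .ndvi import MEADOW, NDVIStack, STEPPE
from .pedotransfer import MODELS
from .profiles import DEFAULT_SCHEME, LayerScheme, SoilLayer, SoilProfileRecord
from .raster import Grid, write_ascii_grid

__all__ = [
    "SyntheticSpec",
    "gen_mask", "gen_ndvi_stack", "gen_trend_stack",
    "gen_soil_profiles", "gen_plot_surveys",
    "write_fixture",
]

# substream ids (stable across versions; changing them changes fixtures)
_STREAM_MASK, _STREAM_NDVI, _STREAM_PROFILES, _STREAM_SURVEYS, _STREAM_TREND = range(5)

#: column order and affine (offset, scale) unit mapping for plot surveys
SURVEY_SCALING = {
    "socd": (6.0, 2.0),            # kg C m^-2
    "biomass": (220.0, 80.0),      # g m^-2
    "moisture": (22.0, 8.0),       # %
    "temperature": (6.0, 3.0),     # degC
    "conductivity": (0.5, 0.15),   # mS cm^-1
    "elevation": (4200.0, 400.0),  # m
}


def _default_corr() -> np.ndarray:
    # socd, biomass, moisture, temperature, conductivity, elevation
    return np.array([
        [1.00, 0.60, 0.70, -0.30, -0.30, -0.40],
        [0.60, 1.00, 0.50, -0.20, -0.20, -0.30],
        [0.70, 0.50, 1.00, -0.25, -0.15, -0.20],
        [-0.30, -0.20, -0.25, 1.00, 0.10, -0.35],
        [-0.30, -0.20, -0.15, 0.10, 1.00, 0.10],
        [-0.40, -0.30, -0.20, -0.35, 0.10, 1.00],
    ])


@dataclass
class SyntheticSpec:
    """Parameters for the synthetic soil-survey / satellite inputs."""

    seed: int = 0
    shape: tuple[int, int] = (50, 50)
    cell_size: float = 10_000.0             # m (10 km pixels)
    years: tuple[int, ...] = tuple(range(2000, 2016))
    steppe_fraction: float = 0.5
    # NDVI stack: per-class (slope mean, slope sd) in NDVI yr^-1, plus noise
    class_slopes: dict = field(default_factory=lambda: {
        "steppe": (0.002, 0.001), "meadow": (0.004, 0.001)})
    ndvi_intercept: tuple[float, float] = (0.35, 0.08)
    ndvi_noise_sd: float = 0.02
    # soil profiles
    n_profiles: int = 200
    generating_model_id: int = 1
    soc_log_mean: float = float(np.log(30.0))   # lognormal true SOC, g kg^-1
    soc_log_sd: float = 0.5
    bd_noise_sd: float = 0.0
    gravel_mean: float = 0.0
    gravel_sd: float = 0.0
    layer_scheme: LayerScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    som_convention: str = "as_printed"
    # plot surveys
    n_surveys: int = 59
    survey_correlation: np.ndarray = field(default_factory=_default_corr)

    def __post_init__(self) -> None:
        if self.ndvi_noise_sd < 0 or self.bd_noise_sd < 0 or self.gravel_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.steppe_fraction <= 1.0):
            raise ValueError("steppe_fraction must be in [0, 1]")
        c = np.asarray(self.survey_correlation, dtype=float)
        if c.shape != (len(SURVEY_SCALING), len(SURVEY_SCALING)):
            raise ValueError("survey_correlation must be 6x6")
        if not np.allclose(c, c.T):
            raise ValueError("survey_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("survey_correlation must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"survey_correlation is not positive semi-definite "
                f"(minimum eigenvalue {eigmin:.3e})")
        self.survey_correlation = c

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def gen_mask(spec: SyntheticSpec) -> Grid:
    """Contiguous steppe (left) / meadow (right) split by column fraction."""
    nrows, ncols = spec.shape
    n_steppe = int(round(ncols * spec.steppe_fraction))
    codes = np.full((nrows, ncols), MEADOW, dtype=np.int16)
    codes[:, :n_steppe] = STEPPE
    return Grid(codes, cell_size=spec.cell_size)


def gen_ndvi_stack(spec: SyntheticSpec, mask: Grid | None = None
                   ) -> tuple[NDVIStack, dict[str, np.ndarray]]:
    """NDVI_i = clip(intercept + slope*i + eps, 0, 1), i = 1..n_years.

    Per-pixel slopes are drawn from the grassland class's normal
    distribution; the truth (intercept and slope grids) is returned for
    recovery tests and never re-read from the generated data.
    """
    if mask is None:
        mask = gen_mask(spec)
    rng = spec.rng(_STREAM_NDVI)
    nrows, ncols = spec.shape
    codes = np.asarray(mask.data)
    intercept = rng.normal(*spec.ndvi_intercept, size=(nrows, ncols))
    slope = np.zeros((nrows, ncols))
    for name, code in (("steppe", STEPPE), ("meadow", MEADOW)):
        mean, sd = spec.class_slopes[name]
        sel = codes == code
        slope[sel] = rng.normal(mean, sd, size=int(sel.sum()))
    n = len(spec.years)
    i = np.arange(1, n + 1)[:, None, None]
    noise = rng.normal(0.0, spec.ndvi_noise_sd, size=(n, nrows, ncols)) \
        if spec.ndvi_noise_sd > 0 else 0.0
    data = np.clip(intercept[None] + slope[None] * i + noise, 0.0, 1.0)
    stack = NDVIStack(years=spec.years, data=data, cell_size=spec.cell_size)
    return stack, {"intercept": intercept, "slope": slope}


def gen_trend_stack(spec: SyntheticSpec, slopes: np.ndarray,
                    intercept: float = 5.0, noise_sd: float = 0.0
                    ) -> np.ndarray:
    """Unclipped annual stack with planted per-pixel slopes (SOCD units).

    Unlike :func:`gen_ndvi_stack` the values are not bounded, so planted
    slopes of any magnitude are recovered exactly at zero noise.
    """
    slopes = np.asarray(slopes, dtype=float)
    if slopes.shape != tuple(spec.shape):
        raise ValueError("slopes grid must match spec.shape")
    rng = spec.rng(_STREAM_TREND)
    n = len(spec.years)
    i = np.arange(1, n + 1)[:, None, None]
    noise = rng.normal(0.0, noise_sd, size=(n,) + tuple(spec.shape)) \
        if noise_sd > 0 else 0.0
    return intercept + slopes[None] * i + noise


def gen_soil_profiles(spec: SyntheticSpec
                      ) -> tuple[list[SoilProfileRecord], pd.DataFrame]:
    """Three-layer profiles whose BD follows the chosen forward model.

    True SOC is lognormal per layer; BD = forward(model, SOC) plus
    truncated Gaussian noise kept inside the model's invertible domain;
    SOM is attached under the spec's convention.  The returned truth
    frame carries the generating SOC so recovery error can be measured
    without re-reading generated files.
    """
    model = MODELS[spec.generating_model_id]
    rng = spec.rng(_STREAM_PROFILES)
    nrows, ncols = spec.shape
    extent_x = ncols * spec.cell_size
    extent_y = nrows * spec.cell_size
    lo, hi = model.bd_domain
    records: list[SoilProfileRecord] = []
    truth_rows = []
    intervals = spec.layer_scheme.intervals()
    for p in range(spec.n_profiles):
        gtype = "steppe" if rng.random() < spec.steppe_fraction else "meadow"
        x = float(rng.uniform(0, extent_x))
        y = float(rng.uniform(-extent_y, 0))
        layers = []
        for li, (top, bottom) in enumerate(intervals, start=1):
            soc = float(rng.lognormal(spec.soc_log_mean, spec.soc_log_sd))
            bd = pedotransfer.forward_bd(model, soc)
            if spec.bd_noise_sd > 0:
                bd += float(rng.normal(0.0, spec.bd_noise_sd))
                bd = float(np.clip(bd, lo + 1e-6, hi))
            gravel = float(np.clip(rng.normal(spec.gravel_mean, spec.gravel_sd),
                                   0.0, 100.0)) if spec.gravel_sd > 0 \
                else float(np.clip(spec.gravel_mean, 0.0, 100.0))
            som = soc * pedotransfer.SOM_TO_SOC_FACTOR \
                if spec.som_convention == "van_bemmelen" \
                else soc * pedotransfer.SOM_CARBON_FRACTION
            layers.append(SoilLayer(top_depth=top, bottom_depth=bottom,
                                    bd=bd, soc=soc, gravel_pct=gravel, som=som))
            truth_rows.append({"site_id": f"site{p:04d}", "layer": f"layer{li}",
                               "true_soc": soc, "bd": bd})
        records.append(SoilProfileRecord(
            site_id=f"site{p:04d}", x=x, y=y, grassland_type=gtype,
            layers=layers))
    return records, pd.DataFrame(truth_rows)


def gen_plot_surveys(spec: SyntheticSpec) -> pd.DataFrame:
    """Plot surveys drawn from a multivariate normal with the target
    correlation structure, affinely mapped to plausible field units
    (correlations preserved)."""
    rng = spec.rng(_STREAM_SURVEYS)
    corr = spec.survey_correlation
    # eigendecomposition root: tolerant of exactly-PSD matrices
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_surveys, corr.shape[0])) @ root.T
    out = {}
    for j, (name, (offset, scale)) in enumerate(SURVEY_SCALING.items()):
        out[name] = offset + scale * z[:, j]
    frame = pd.DataFrame(out)
    frame.insert(0, "plot_id", [f"plot{i:03d}" for i in range(spec.n_surveys)])
    return frame


def profiles_to_frame(records: list[SoilProfileRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for lyr in rec.layers:
            rows.append({
                "site_id": rec.site_id, "x": rec.x, "y": rec.y,
                "grassland_type": rec.grassland_type,
                "top_cm": lyr.top_depth, "bottom_cm": lyr.bottom_depth,
                "bd": lyr.bd, "soc": lyr.soc, "gravel_pct": lyr.gravel_pct,
                "som": lyr.som,
            })
    return pd.DataFrame(rows)


def frame_to_profiles(frame: pd.DataFrame) -> list[SoilProfileRecord]:
    records = []
    for site_id, group in frame.groupby("site_id", sort=True):
        layers = [
            SoilLayer(top_depth=r.top_cm, bottom_depth=r.bottom_cm, bd=r.bd,
                      soc=r.soc, gravel_pct=r.gravel_pct,
                      som=None if pd.isna(r.som) else float(r.som))
            for r in group.itertuples()
        ]
        first = group.iloc[0]
        records.append(SoilProfileRecord(
            site_id=str(site_id), x=float(first.x), y=float(first.y),
            grassland_type=str(first.grassland_type), layers=layers))
    return records


def write_fixture(spec: SyntheticSpec, outdir: str | Path) -> dict[str, str]:
    """Write a self-contained plain-text fixture directory.

    Emits the grassland mask and per-year NDVI as ASCII grids, profile
    and survey tables as CSV, truth grids as ASCII grids and scalar
    truth/spec metadata as JSON.  Byte-identical across runs for a fixed
    spec and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = gen_mask(spec)
    stack, ndvi_truth = gen_ndvi_stack(spec, mask)
    profs, soil_truth = gen_soil_profiles(spec)
    surveys = gen_plot_surveys(spec)

    paths: dict[str, str] = {}

    def _save_grid(name: str, grid: Grid, fmt: str = "%.17g") -> None:
        path = outdir / name
        write_ascii_grid(grid, path, fmt=fmt)
        paths[name] = str(path)

    _save_grid("mask.asc", mask, fmt="%d")
    for year in stack.years:
        _save_grid(f"ndvi_{year}.asc", stack.grid(year))
    _save_grid("truth_slope.asc", Grid(ndvi_truth["slope"], spec.cell_size))
    _save_grid("truth_intercept.asc", Grid(ndvi_truth["intercept"], spec.cell_size))

    for name, frame in (("profiles.csv", profiles_to_frame(profs)),
                        ("soil_truth.csv", soil_truth),
                        ("surveys.csv", surveys)):
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.17g")
        paths[name] = str(path)

    meta = asdict(spec)
    meta["survey_correlation"] = spec.survey_correlation.tolist()
    meta["layer_scheme"] = list(spec.layer_scheme.boundaries)
    meta["years"] = list(spec.years)
    meta["shape"] = list(spec.shape)
    meta_path = outdir / "spec.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["spec.json"] = str(meta_path)
    return paths
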