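"""Per-layer and 0-30 cm soil organic carbon density for soil profiles.

A layer's SOCD is the depth-weighted, gravel-corrected mass

    SOCD_i = T_i * BD_i * SOC_i * (1 - C_i/100) / 100   [kg C m^-2]

with thickness T in cm, BD in g cm^-3, SOC in g kg^-1 and gravel
fraction C in %.  A profile total is the straight sum over layers.
Profiles with arbitrary layering are first re-sliced onto a fixed
three-layer scheme (default boundaries 0 / 9.1 / 16.6 / 30 cm) by
thickness-weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import pedotransfer
from .pedotransfer import MODELS, FLAG_OK

__all__ = [
    "SoilLayer",
    "SoilProfileRecord",
    "LayerScheme",
    "DEFAULT_SCHEME",
    "ProfileCoverageError",
    "reslice_profile",
    "layer_socd",
    "profile_socd",
    "batch_socd",
    "group_means",
]

_EPS = 1e-9


class ProfileCoverageError(ValueError):
    """Raised when a profile does not cover a requested depth interval."""


@dataclass(frozen=True)
class SoilLayer:
    top_depth: float          # cm
    bottom_depth: float       # cm
    bd: float                 # g cm^-3
    soc: float                # g kg^-1
    gravel_pct: float = 0.0   # % of fraction > 2 mm
    som: float | None = None  # g kg^-1, optional (SOM-method input)
    gravel_known: bool = True

    def __post_init__(self) -> None:
        if self.bottom_depth <= self.top_depth:
            raise ValueError("bottom_depth must exceed top_depth")
        if not (0 <= self.gravel_pct <= 100):
            raise ValueError("gravel_pct must be in [0, 100]")
        if self.bd <= 0:
            raise ValueError("bd must be positive")
        if self.soc < 0:
            raise ValueError("soc must be non-negative")

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth


@dataclass
class SoilProfileRecord:
    site_id: str
    x: float
    y: float
    grassland_type: str                 # "steppe" | "meadow"
    layers: list[SoilLayer]
    source_method: str = "measured_soc"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        layers = sorted(self.layers, key=lambda l: l.top_depth)
        if abs(layers[0].top_depth) > _EPS:
            raise ValueError("layers must start at 0 cm")
        for upper, lower in zip(layers, layers[1:]):
            if abs(upper.bottom_depth - lower.top_depth) > _EPS:
                raise ValueError(
                    f"layers must be contiguous; gap/overlap at "
                    f"{upper.bottom_depth}-{lower.top_depth} cm"
                )
        self.layers = layers

    @property
    def total_depth(self) -> float:
        return self.layers[-1].bottom_depth

    def covers(self, depth: float) -> bool:
        return self.total_depth >= depth - _EPS


@dataclass(frozen=True)
class LayerScheme:
    """Ordered slicing boundaries in cm, starting at 0."""

    boundaries: tuple[float, ...] = (0.0, 9.1, 16.6, 30.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2 or abs(b[0]) > _EPS:
            raise ValueError("boundaries must start at 0 with >= 2 entries")
        if any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return len(self.boundaries) - 1

    @property
    def total_depth(self) -> float:
        return self.boundaries[-1]

    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.boundaries, self.boundaries[1:]))


DEFAULT_SCHEME = LayerScheme()


def reslice_profile(profile: SoilProfileRecord,
                    scheme: LayerScheme = DEFAULT_SCHEME) -> SoilProfileRecord:
    """Re-slice a profile onto scheme boundaries.

    Target-layer bd/soc/gravel are thickness-weighted means of the
    overlapping source layers, so piecewise-constant fields (and the
    thickness*bd mass for piecewise-constant bd) are conserved.
    """
    if not profile.covers(scheme.total_depth):
        raise ProfileCoverageError(
            f"profile {profile.site_id!r} covers 0-{profile.total_depth} cm, "
            f"missing {profile.total_depth}-{scheme.total_depth} cm"
        )
    new_layers = []
    for top, bottom in scheme.intervals():
        w_total = 0.0
        bd = soc = gravel = 0.0
        som_acc = 0.0
        som_ok = all(l.som is not None for l in profile.layers)
        gravel_known = True
        for src in profile.layers:
            overlap = min(bottom, src.bottom_depth) - max(top, src.top_depth)
            if overlap <= _EPS:
                continue
            w_total += overlap
            bd += overlap * src.bd
            soc += overlap * src.soc
            gravel += overlap * src.gravel_pct
            gravel_known &= src.gravel_known
            if som_ok:
                som_acc += overlap * src.som
        if bottom - top - w_total > _EPS:
            raise ProfileCoverageError(
                f"profile {profile.site_id!r}: no data for {top}-{bottom} cm"
            )
        new_layers.append(
            SoilLayer(
                top_depth=top,
                bottom_depth=bottom,
                bd=bd / w_total,
                soc=soc / w_total,
                gravel_pct=gravel / w_total,
                som=(som_acc / w_total) if som_ok else None,
                gravel_known=gravel_known,
            )
        )
    return replace(profile, layers=new_layers)


def layer_socd(layer: SoilLayer) -> float:
    """SOCD of one layer in kg C m^-2: T*BD*SOC*(1 - C/100)/100."""
    return (layer.thickness * layer.bd * layer.soc
            * (1.0 - layer.gravel_pct / 100.0) / 100.0)


def profile_socd(profile: SoilProfileRecord,
                 scheme: LayerScheme = DEFAULT_SCHEME) -> tuple[list[float], float]:
    """Per-scheme-layer SOCD values and their exact sum, kg C m^-2."""
    sliced = reslice_profile(profile, scheme)
    per_layer = [layer_socd(l) for l in sliced.layers]
    return per_layer, float(sum(per_layer))


_BD_MODEL_CHOICES = {f"bd_model_{k}": k for k in MODELS}


def _layer_soc_for_method(layer: SoilLayer, model_choice: str,
                          out_of_domain_policy: str,
                          som_convention: str) -> tuple[float, str]:
    """SOC (g kg^-1) of one layer under the requested estimation route."""
    if model_choice == "measured":
        return layer.soc, FLAG_OK
    if model_choice == "som":
        if layer.som is None:
            return np.nan, "som_missing"
        return pedotransfer.soc_from_som(layer.som, som_convention), FLAG_OK
    if model_choice in _BD_MODEL_CHOICES:
        model = MODELS[_BD_MODEL_CHOICES[model_choice]]
        return pedotransfer.invert_soc(model, layer.bd, out_of_domain_policy)
    raise ValueError(f"unknown model_choice {model_choice!r}")


def batch_socd(profiles: Iterable[SoilProfileRecord],
               model_choice: str = "measured",
               scheme: LayerScheme = DEFAULT_SCHEME,
               out_of_domain_policy: str = "missing",
               som_convention: str = "as_printed") -> pd.DataFrame:
    """SOCD for every profile x scheme layer under one estimation method.

    Returns a long table with one row per profile and layer plus a
    ``total`` row per profile; inversion failures propagate as flagged
    rows with NaN SOCD.  Profiles not covering the scheme are emitted
    with flag ``incomplete_coverage`` and excluded from totals.
    """
    rows = []
    for profile in profiles:
        base = {
            "site_id": profile.site_id,
            "grassland_type": profile.grassland_type,
            "method": model_choice,
        }
        try:
            sliced = reslice_profile(profile, scheme)
        except ProfileCoverageError:
            rows.append({**base, "layer": "total", "top_cm": 0.0,
                         "bottom_cm": scheme.total_depth, "socd": np.nan,
                         "flag": "incomplete_coverage"})
            continue
        total = 0.0
        total_flag = FLAG_OK
        for idx, lyr in enumerate(sliced.layers, start=1):
            soc, flag = _layer_soc_for_method(
                lyr, model_choice, out_of_domain_policy, som_convention)
            socd = layer_socd(replace_soc(lyr, soc)) if np.isfinite(soc) else np.nan
            if not np.isfinite(socd):
                total = np.nan
                if total_flag == FLAG_OK:
                    total_flag = flag
            else:
                total += socd
            if not lyr.gravel_known and flag == FLAG_OK:
                flag = "gravel_assumed_zero"
            rows.append({**base, "layer": f"layer{idx}", "top_cm": lyr.top_depth,
                         "bottom_cm": lyr.bottom_depth, "socd": socd, "flag": flag})
        rows.append({**base, "layer": "total", "top_cm": 0.0,
                     "bottom_cm": scheme.total_depth, "socd": total,
                     "flag": total_flag})
    return pd.DataFrame(rows, columns=["site_id", "grassland_type", "method",
                                       "layer", "top_cm", "bottom_cm", "socd",
                                       "flag"])


def replace_soc(layer: SoilLayer, soc: float) -> SoilLayer:
    return replace(layer, soc=float(soc))


def group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Missing-aware mean SOCD by grassland type, method and layer.

    Flagged (NaN) rows are dropped before averaging; strata with no
    valid rows are absent rather than zero.
    """
    valid = table.dropna(subset=["socd"])
    if valid.empty:
        return pd.DataFrame(columns=["grassland_type", "method", "layer",
                                     "mean_socd", "n"])
    grouped = (valid.groupby(["grassland_type", "method", "layer"], sort=True)
               .agg(mean_socd=("socd", "mean"), n=("socd", "size"))
               .reset_index())
    return grouped


def qc_report(table: pd.DataFrame) -> list[dict]:
    """JSON-lines-ready QC records: one entry per flagged (excluded) row."""
    flagged = table[table["flag"] != FLAG_OK]
    return flagged.to_dict(orient="records")
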