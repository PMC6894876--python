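"""Empirical bulk-density / organic-carbon pedotransfer models.

Four published exponential BD(SOC) models are shipped as frozen
constants.  Each has the form

    BD = c + a * exp(-b * SOC)

with ``c = 0`` for the pure-exponential variants.  The forward map is
strictly decreasing in SOC for ``b > 0``, so it has a closed-form
inverse

    SOC = -ln((BD - c) / a) / b

valid on the half-open BD domain ``(c, a + c]``.  Bulk densities at or
below the asymptote ``c`` have no finite preimage; densities above the
intercept ``a + c`` would imply negative SOC and are handled by an
explicit out-of-domain policy.

Also housed here: the SOM/SOC conversion (both printed and conventional
van Bemmelen directions), the dichromate-titration SOM reduction and the
cylinder-core bulk-density reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PedotransferModel",
    "MODELS",
    "TitrationRecord",
    "CoreSampleRecord",
    "forward_bd",
    "invert_soc",
    "soc_from_som",
    "som_from_titration",
    "bd_from_core",
    "invert_table",
    "FLAG_OK",
    "FLAG_BELOW_ASYMPTOTE",
    "FLAG_ABOVE_INTERCEPT",
    "FLAG_CLAMPED",
]

# inversion status codes (machine-readable, never silently dropped)
FLAG_OK = "ok"
FLAG_BELOW_ASYMPTOTE = "below_asymptote"          # bd <= c: no finite SOC
FLAG_ABOVE_INTERCEPT = "above_intercept"          # bd > a + c: SOC would be < 0
FLAG_CLAMPED = "above_intercept_clamped"          # same, clamped to SOC = 0

SOM_TO_SOC_FACTOR = 1.724          # conventional van Bemmelen mass ratio
SOM_CARBON_FRACTION = 0.58         # = 1 / 1.724, printed-equation coefficient


@dataclass(frozen=True)
class PedotransferModel:
    """One exponential BD(SOC) model: ``BD = c + a * exp(-b * SOC)``.

    Parameters
    ----------
    model_id : int or str
        Registry key (1-4 for the shipped models).
    a : float
        Amplitude, g cm^-3.
    b : float
        Decay rate, kg g^-1.
    c : float
        Asymptotic bulk density at high SOC, g cm^-3 (0 for the
        pure-exponential form).
    """

    model_id: int | str
    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c < 0:
            raise ValueError("require a > 0, b > 0, c >= 0")

    @property
    def form(self) -> str:
        return "offset_exp" if self.c > 0 else "pure_exp"

    @property
    def bd_domain(self) -> tuple[float, float]:
        """Half-open BD interval ``(c, a + c]`` with a finite SOC >= 0 inverse."""
        return (self.c, self.a + self.c)

    def forward(self, soc):
        return forward_bd(self, soc)

    def invert(self, bd, out_of_domain_policy: str = "missing"):
        return invert_soc(self, bd, out_of_domain_policy)


#: The four shipped models (BD in g cm^-3, SOC in g kg^-1).
MODELS: dict[int, PedotransferModel] = {
    1: PedotransferModel(1, a=1.28, b=0.01724, c=0.3),
    2: PedotransferModel(2, a=1.515, b=0.102),
    3: PedotransferModel(3, a=0.5427, b=0.077, c=0.9955),
    4: PedotransferModel(4, a=1.4055, b=0.1039),
}


def forward_bd(model: PedotransferModel, soc):
    """Evaluate BD = c + a*exp(-b*SOC) for SOC in g kg^-1.

    Accepts scalars or arrays; raises ``ValueError`` on negative or
    non-finite SOC.
    """
    soc_arr = np.asarray(soc, dtype=float)
    if not np.all(np.isfinite(soc_arr)):
        raise ValueError("soc must be finite")
    if np.any(soc_arr < 0):
        raise ValueError("soc must be non-negative")
    out = model.c + model.a * np.exp(-model.b * soc_arr)
    return out if np.ndim(soc) else float(out)


def invert_soc(model: PedotransferModel, bd, out_of_domain_policy: str = "missing"):
    """Closed-form inverse SOC(BD) with explicit out-of-domain handling.

    Parameters
    ----------
    model : PedotransferModel
    bd : float or array_like
        Bulk density, g cm^-3; must be finite and positive.
    out_of_domain_policy : {"missing", "clamp_zero"}
        For ``bd`` above the model intercept ``a + c`` (negative implied
        SOC): return NaN (``missing``) or 0 (``clamp_zero``), flagged
        either way.  ``bd <= c`` is always missing with reason
        ``below_asymptote``.

    Returns
    -------
    (soc, flag)
        SOC in g kg^-1 (NaN where missing) and a status-code string, or
        arrays of both for array input.
    """
    if out_of_domain_policy not in {"missing", "clamp_zero"}:
        raise ValueError(f"unknown policy {out_of_domain_policy!r}")
    bd_arr = np.asarray(bd, dtype=float)
    if not np.all(np.isfinite(bd_arr)):
        raise ValueError("bd must be finite")
    if np.any(bd_arr <= 0):
        raise ValueError("bd must be positive")

    lo, hi = model.bd_domain
    soc = np.full(bd_arr.shape, np.nan)
    flags = np.full(bd_arr.shape, FLAG_OK, dtype=object)

    in_dom = (bd_arr > lo) & (bd_arr <= hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        soc[in_dom] = -np.log((bd_arr[in_dom] - model.c) / model.a) / model.b

    below = bd_arr <= lo
    flags[below] = FLAG_BELOW_ASYMPTOTE

    above = bd_arr > hi
    if out_of_domain_policy == "clamp_zero":
        soc[above] = 0.0
        flags[above] = FLAG_CLAMPED
    else:
        flags[above] = FLAG_ABOVE_INTERCEPT

    if np.ndim(bd):
        return soc, flags
    return float(soc), str(flags[()])


def soc_from_som(som, convention: str = "as_printed"):
    """Convert soil organic matter to soil organic carbon (g kg^-1).

    ``as_printed`` inverts SOM = SOC * 0.58, i.e. SOC = SOM / 0.58.
    ``van_bemmelen`` inverts SOM = 1.724 * SOC, i.e. SOC = 0.58 * SOM.
    """
    som_arr = np.asarray(som, dtype=float)
    if np.any(som_arr < 0):
        raise ValueError("som must be non-negative")
    if convention == "as_printed":
        out = som_arr / SOM_CARBON_FRACTION
    elif convention == "van_bemmelen":
        out = som_arr / SOM_TO_SOC_FACTOR
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return out if np.ndim(som) else float(out)


@dataclass(frozen=True)
class TitrationRecord:
    """Dichromate-titration bookkeeping for one soil sample.

    a_blank / b_sample are the Fe2+ standard volumes (mL) of blank and
    sample titrations, n_fe the equivalent concentration, w_dry the dry
    sample weight in g.
    """

    a_blank: float
    b_sample: float
    n_fe: float
    w_dry: float

    def __post_init__(self) -> None:
        if not (self.a_blank >= self.b_sample >= 0):
            raise ValueError("require a_blank >= b_sample >= 0")
        if self.w_dry <= 0:
            raise ValueError("w_dry must be positive")
        if self.n_fe <= 0:
            raise ValueError("n_fe must be positive")


def som_from_titration(rec: TitrationRecord) -> float:
    """SOM (g kg^-1) from a titration record.

    (a - b) * N_Fe * 0.003 * 1.724 * 1.08 / W gives g organic matter per
    g dry soil; the result is scaled by 1000 to the package-wide
    g kg^-1 mass convention.
    """
    per_g = (rec.a_blank - rec.b_sample) * rec.n_fe * 0.003 * 1.724 * 1.08 / rec.w_dry
    return per_g * 1000.0


@dataclass(frozen=True)
class CoreSampleRecord:
    """Cylinder-core weights/volume for a bulk-density determination."""

    m_total: float     # cylinder + soil, g
    g_cyl: float       # cylinder, g
    v_cyl: float       # cylinder volume, cm^3
    w_pct: float       # soil water content, %

    def __post_init__(self) -> None:
        if self.m_total < self.g_cyl:
            raise ValueError("m_total must be >= g_cyl")
        if self.v_cyl <= 0:
            raise ValueError("v_cyl must be positive")
        if self.w_pct < 0:
            raise ValueError("w_pct must be non-negative")


def bd_from_core(rec: CoreSampleRecord) -> float:
    """Dry bulk density (g cm^-3) = (M - G) * 100 / V / (100 + W)."""
    return (rec.m_total - rec.g_cyl) * 100.0 / rec.v_cyl / (100.0 + rec.w_pct)


def invert_table(table: pd.DataFrame, model: PedotransferModel,
                 out_of_domain_policy: str = "missing",
                 bd_column: str = "bd") -> pd.DataFrame:
    """Batch inversion over a delimited table; adds ``soc`` and ``flag`` columns."""
    soc, flags = invert_soc(model, table[bd_column].to_numpy(dtype=float),
                            out_of_domain_policy)
    out = table.copy()
    out["soc"] = soc
    out["flag"] = flags
    return out


def model_registry_frame(models: Iterable[PedotransferModel] | None = None) -> pd.DataFrame:
    """Serializable registry view (id, form, a, b, c) for config export."""
    models = list(models) if models is not None else list(MODELS.values())
    return pd.DataFrame(
        {
            "model_id": [m.model_id for m in models],
            "form": [m.form for m in models],
            "a": [m.a for m in models],
            "b": [m.b for m in models],
            "c": [m.c for m in models],
        }
    )
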