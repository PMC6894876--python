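"""Pearson correlation screening of SOCD against environmental drivers.

Implements the textbook product-moment coefficient and a two-sided
t-test significance flag at the 0.01 / 0.05 levels, with pairwise
deletion of missing values and an optional multiple-testing correction
(off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_r", "significance", "correlation_matrix",
    "CorrelationResult", "long_format",
    "FLAG_P01", "FLAG_P05", "FLAG_NS", "FLAG_UNDEFINED",
]

FLAG_P01 = "p<0.01"
FLAG_P05 = "p<0.05"
FLAG_NS = "ns"
FLAG_UNDEFINED = "undefined"

#: canonical plot-survey columns
SURVEY_COLUMNS = ("socd", "biomass", "moisture", "temperature",
                  "conductivity", "elevation")


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (undefined) for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if den == 0:
        return np.nan
    return float(np.clip((dx * dy).sum() / den, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p of the t transform t = r*sqrt((n-2)/(1-r^2)), n-2 df."""
    if not np.isfinite(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def significance(r: float, n: int) -> str:
    """Two-level flag from the two-sided t-test; |r| = 1 counts as p<0.01."""
    if n < 3:
        raise ValueError("need n >= 3")
    p = correlation_p(r, n)
    if not np.isfinite(p):
        return FLAG_UNDEFINED
    if p < 0.01:
        return FLAG_P01
    if p < 0.05:
        return FLAG_P05
    return FLAG_NS


@dataclass
class CorrelationResult:
    r: pd.DataFrame          # symmetric, unit diagonal
    p: pd.DataFrame
    flags: pd.DataFrame      # p<0.01 / p<0.05 / ns / undefined
    n: pd.DataFrame          # pairwise-complete sample sizes


def correlation_matrix(table: pd.DataFrame, columns=None,
                       correction: str | None = None,
                       alpha_levels: tuple[float, float] = (0.01, 0.05)
                       ) -> CorrelationResult:
    """All pairwise correlations with significance flags.

    Missing values are removed pairwise and the per-pair n reported.
    ``correction`` may be ``"bonferroni"`` (p scaled by the number of
    off-diagonal pairs) — default None, matching plain screening.
    Constant columns yield undefined (NaN) entries off the diagonal.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    m = len(cols)
    r = np.eye(m)
    p = np.zeros((m, m))
    n_mat = np.zeros((m, m), dtype=int)
    flags = np.full((m, m), FLAG_P01, dtype=object)
    n_tests = m * (m - 1) // 2
    for a in range(m):
        n_mat[a, a] = int(table[cols[a]].notna().sum())
        for b in range(a + 1, m):
            pair = table[[cols[a], cols[b]]].dropna()
            n = len(pair)
            n_mat[a, b] = n_mat[b, a] = n
            if n < 3:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                flags[a, b] = flags[b, a] = FLAG_UNDEFINED
                continue
            rv = pearson_r(pair[cols[a]].to_numpy(), pair[cols[b]].to_numpy())
            pv = correlation_p(rv, n)
            if correction == "bonferroni" and np.isfinite(pv):
                pv = min(1.0, pv * n_tests)
            r[a, b] = r[b, a] = rv
            p[a, b] = p[b, a] = pv
            if not np.isfinite(rv):
                flag = FLAG_UNDEFINED
            elif pv < alpha_levels[0]:
                flag = FLAG_P01
            elif pv < alpha_levels[1]:
                flag = FLAG_P05
            else:
                flag = FLAG_NS
            flags[a, b] = flags[b, a] = flag
    idx = pd.Index(cols)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        flags=pd.DataFrame(flags, index=idx, columns=idx),
        n=pd.DataFrame(n_mat, index=idx, columns=idx),
    )


def long_format(result: CorrelationResult) -> pd.DataFrame:
    """Long table (var1, var2, r, n, p, flag) over the upper triangle."""
    cols = list(result.r.columns)
    rows = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            rows.append({
                "var1": cols[a],
                "var2": cols[b],
                "r": result.r.iloc[a, b],
                "n": result.n.iloc[a, b],
                "p": result.p.iloc[a, b],
                "flag": result.flags.iloc[a, b],
            })
    return pd.DataFrame(rows)
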