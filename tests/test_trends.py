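import collections

import numpy as np
import pandas as pd
import pytest

from grasscarbon.ndvi import MEADOW, OTHER, STEPPE
from grasscarbon.raster import Grid
from grasscarbon.trends import (
    CLASS_LABELS,
    NODATA_CLASS,
    AnnualSeries,
    class_area_table,
    classify_trend,
    mann_kendall,
    ols_slope,
    regional_series,
    sen_beta,
    trend_raster,
)


def mk_oracle(x):
    """Brute-force pair enumeration + textbook tie-corrected variance."""
    x = [v for v in x if np.isfinite(v)]
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]))
    var = n * (n - 1) * (2 * n + 5) / 18.0
    for cnt in collections.Counter(x).values():
        var -= cnt * (cnt - 1) * (2 * cnt + 5) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return s, z


class TestOlsSlope:
    def test_exact_linear(self):
        i = np.arange(1, 11)
        assert ols_slope(2 + 0.5 * i) == pytest.approx(0.5, abs=1e-12)

    def test_matches_polyfit_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            i = np.arange(1, 13)
            assert ols_slope(x) == pytest.approx(np.polyfit(i, x, 1)[0],
                                                 rel=1e-9, abs=1e-12)

    def test_constant_series(self):
        assert ols_slope(np.full(8, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_reversal_antisymmetry(self):
        x = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        assert ols_slope(x[::-1]) == pytest.approx(-ols_slope(x), abs=1e-12)

    def test_missing_handled(self):
        x = np.array([1.0, np.nan, 3.0, 4.0])
        # fit on available (i, value) pairs
        assert ols_slope(x) == pytest.approx(
            np.polyfit([1, 3, 4], [1.0, 3.0, 4.0], 1)[0], rel=1e-9)

    def test_degenerate(self):
        assert np.isnan(ols_slope(np.array([np.nan, np.nan])))
        assert np.isnan(ols_slope(np.array([1.0])))


class TestMannKendall:
    def test_increasing_n10(self):
        s, z, sig = mann_kendall(np.arange(10.0))
        assert s == 45
        assert z == pytest.approx(44 / np.sqrt(125.0), rel=1e-12)
        assert sig == "sig_increase"

    def test_all_equal(self):
        s, z, sig = mann_kendall(np.full(10, 2.0))
        assert s == 0 and z == 0.0 and sig == "none"

    def test_decreasing_antisymmetric(self):
        s, z, sig = mann_kendall(np.arange(10.0)[::-1])
        assert s == -45
        assert z == pytest.approx(-44 / np.sqrt(125.0), rel=1e-12)
        assert sig == "sig_decrease"

    def test_too_short(self):
        with pytest.raises(ValueError):
            mann_kendall(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            mann_kendall(np.array([1.0, np.nan, np.nan, 2.0]))

    def test_oracle_agreement_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            x = rng.integers(0, 5, size=n).astype(float)  # many ties
            s, z, _ = mann_kendall(x)
            s0, z0 = mk_oracle(x)
            assert s == s0
            assert z == pytest.approx(z0, abs=1e-12)

    def test_missing_uses_available_pairs(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        s, _, _ = mann_kendall(x)
        assert s == 6


class TestSenBeta:
    def test_enumeration_example(self):
        assert sen_beta(np.array([1.0, 2.0, 4.0])) == 1.5

    def test_exact_linear(self):
        i = np.arange(1, 9)
        assert sen_beta(3 - 0.25 * i) == pytest.approx(-0.25, abs=1e-12)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=10)
        assert sen_beta(x + 100.0) == pytest.approx(sen_beta(x), abs=1e-9)

    def test_sign_matches_s(self, rng):
        for _ in range(50):
            x = rng.normal(size=8)
            s, _, _ = mann_kendall(x)
            beta = sen_beta(x)
            if s != 0:
                assert np.sign(beta) == np.sign(s)


class TestClassify:
    @pytest.mark.parametrize("slope,label", [
        (-0.2, "significant_decrease"),
        (-0.1, "non_significant_decrease"),      # boundary: -0.1 <= s < -0.01
        (-0.05, "non_significant_decrease"),
        (-0.01, "nearly_unchangeable"),          # boundary: -0.01 <= s < 0.01
        (0.0, "nearly_unchangeable"),
        (0.009999, "nearly_unchangeable"),
        (0.01, "non_significant_increase"),      # boundary: 0.01 <= s < 0.1
        (0.05, "non_significant_increase"),
        (0.1, "significant_increase"),           # boundary: s >= 0.1
        (0.5, "significant_increase"),
    ])
    def test_boundaries_half_open(self, slope, label):
        assert classify_trend(slope) == label

    def test_nodata_passthrough(self):
        assert classify_trend(np.nan) is None
        codes = classify_trend(np.array([np.nan, 0.05]))
        assert codes[0] == NODATA_CLASS
        assert CLASS_LABELS[codes[1]] == "non_significant_increase"


def planted_stack(slopes, n_years=16, intercept=5.0):
    i = np.arange(1, n_years + 1)[:, None, None]
    return intercept + np.asarray(slopes)[None] * i


class TestTrendRaster:
    def test_uniform_slope_single_class(self):
        slopes = np.full((5, 5), 0.05)
        res = trend_raster(planted_stack(slopes))
        np.testing.assert_allclose(res.slope.data, 0.05, atol=1e-12)
        table = res.class_areas.set_index("class")["total"]
        assert table["non_significant_increase"] == pytest.approx(100.0)

    def test_half_and_half(self):
        slopes = np.full((4, 4), 0.2)
        slopes[2:] = -0.2
        res = trend_raster(planted_stack(slopes))
        table = res.class_areas.set_index("class")["total"]
        assert table["significant_increase"] == pytest.approx(50.0)
        assert table["significant_decrease"] == pytest.approx(50.0)

    def test_nodata_pixel_excluded(self):
        stack = planted_stack(np.full((2, 2), 0.05))
        stack[:, 0, 0] = np.nan
        res = trend_raster(stack)
        assert res.classes.data[0, 0] == NODATA_CLASS
        table = res.class_areas.set_index("class")["total"]
        assert table["non_significant_increase"] == pytest.approx(100.0)
        assert table.sum() == pytest.approx(100.0, abs=0.01)

    def test_mask_strata_percentages(self):
        slopes = np.zeros((4, 4))
        slopes[:, 2:] = 0.2
        mask = Grid(np.where(np.arange(4)[None, :] < 2, STEPPE, MEADOW)
                    * np.ones((4, 1), dtype=int))
        res = trend_raster(planted_stack(slopes), mask=mask)
        table = res.class_areas.set_index("class")
        assert table.loc["nearly_unchangeable", "steppe"] == pytest.approx(100.0)
        assert table.loc["significant_increase", "meadow"] == pytest.approx(100.0)
        for col in ("steppe", "meadow", "total"):
            assert table[col].sum() == pytest.approx(100.0, abs=0.01)

    def test_other_class_excluded(self):
        mask = Grid(np.full((3, 3), OTHER, dtype=int))
        mask.data[0, 0] = STEPPE
        res = trend_raster(planted_stack(np.zeros((3, 3))), mask=mask)
        assert (res.classes.data[mask.data == OTHER] == NODATA_CLASS).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            trend_raster(np.zeros((2, 3, 3)))           # too few years
        with pytest.raises(ValueError):
            trend_raster(np.zeros((4, 3, 3)), mask=Grid(np.zeros((2, 2))))

    def test_mk_and_sen_grids_consistent(self, rng):
        stack = rng.normal(size=(10, 3, 3))
        res = trend_raster(stack)
        for r in range(3):
            for c in range(3):
                s, z, _ = mann_kendall(stack[:, r, c])
                assert res.mk_s.data[r, c] == s
                assert res.mk_z.data[r, c] == pytest.approx(z, abs=1e-12)
                assert res.sen.data[r, c] == pytest.approx(
                    sen_beta(stack[:, r, c]), abs=1e-12)


class TestRegionalSeries:
    def test_constant_maps(self):
        stack = np.full((4, 3, 3), 2.5)
        mask = Grid(np.full((3, 3), STEPPE, dtype=int))
        series = regional_series(stack, mask, STEPPE)
        np.testing.assert_allclose(series.values, 2.5)

    def test_single_pixel(self):
        stack = np.zeros((4, 2, 2))
        stack[:, 1, 1] = [1.0, 2.0, 3.0, 4.0]
        mask = Grid(np.array([[OTHER, OTHER], [OTHER, MEADOW]]))
        series = regional_series(stack, mask, MEADOW)
        np.testing.assert_allclose(series.values, [1, 2, 3, 4])

    def test_uniform_slope_recovered_by_mean(self):
        slopes = np.full((5, 5), 0.07)
        stack = planted_stack(slopes)
        mask = Grid(np.full((5, 5), MEADOW, dtype=int))
        series = regional_series(stack, mask, MEADOW)
        assert ols_slope(series) == pytest.approx(0.07, abs=1e-12)

    def test_empty_stratum(self):
        with pytest.raises(ValueError):
            regional_series(np.zeros((4, 2, 2)),
                            Grid(np.full((2, 2), STEPPE, dtype=int)), MEADOW)
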