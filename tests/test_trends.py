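"""Five-step trend chain: monthly means, climatology, anomalies, X11,
linear trends."""

import numpy as np
import pandas as pd
import pytest

from sohotspots.grid import build_grid
from sohotspots.synthetic import default_sst_trend_field, gen_env_series
from sohotspots.trends import (
    Climatology,
    DecompositionError,
    MonthlySeries,
    anomalies,
    compute_climatology,
    henderson_weights,
    linear_trend,
    monthly_mean_field,
    to_monthly,
    trend_for_series,
    trend_map,
    x11_decompose,
)


def _series(values, start=(1990, 1)):
    n = len(values)
    key = start[0] * 12 + (start[1] - 1) + np.arange(n)
    return MonthlySeries(key // 12, key % 12 + 1, np.asarray(values, dtype=float))


class TestToMonthly:
    def test_constant_month(self):
        daily = pd.DataFrame(
            {"year": [2000] * 31, "month": [1] * 31, "value": [3.5] * 31}
        )
        series = to_monthly(daily)
        assert len(series) == 1
        assert series.values[0] == pytest.approx(3.5)

    def test_gap_months_preserved_as_missing(self):
        daily = pd.DataFrame(
            {"year": [2000, 2000], "month": [1, 3], "value": [1.0, 2.0]}
        )
        series = to_monthly(daily)
        assert len(series) == 3
        assert np.isnan(series.values[1])

    def test_brute_force_month_grouping(self, rng):
        n = 2000
        dates = pd.to_datetime("2000-01-01") + pd.to_timedelta(
            rng.integers(0, 365 * 3, n), unit="D"
        )
        values = rng.standard_normal(n)
        daily = pd.DataFrame({"date": dates, "value": values})
        series = to_monthly(daily)
        frame = daily.assign(y=dates.year, m=dates.month)
        for (y, m), group in frame.groupby(["y", "m"]):
            idx = np.flatnonzero((series.year == y) & (series.month == m))[0]
            assert series.values[idx] == pytest.approx(group["value"].mean())


class TestClimatologyAndAnomalies:
    def test_constant_series(self):
        series = _series([2.0] * 120)
        clim = compute_climatology(series, (1990, 1999))
        assert np.allclose(clim.month_means, 2.0)

    def test_pure_cycle_recovered(self):
        cycle = np.sin(2 * np.pi * np.arange(12) / 12)
        series = _series(np.tile(cycle, 10))
        clim = compute_climatology(series, (1990, 1999))
        assert np.allclose(clim.month_means, cycle, atol=1e-12)
        anom = anomalies(series, clim)
        assert np.allclose(anom.values, 0.0, atol=1e-12)

    def test_trended_series_matches_per_month_average(self, rng):
        values = rng.standard_normal(240) + 0.01 * np.arange(240)
        series = _series(values)
        clim = compute_climatology(series, (1992, 2005))
        for m in range(1, 13):
            sel = (series.month == m) & (series.year >= 1992) & (series.year <= 2005)
            assert clim.month_means[m - 1] == pytest.approx(values[sel].mean())

    def test_constant_offset_gives_constant_anomaly(self):
        cycle = np.cos(2 * np.pi * np.arange(12) / 12)
        series = _series(np.tile(cycle, 10) + 1.7)
        clim = Climatology(cycle, (1990, 1999))
        anom = anomalies(series, clim)
        assert np.allclose(anom.values, 1.7)

    def test_missing_reference_month_raises(self):
        values = np.arange(120, dtype=float)
        values[np.arange(120) % 12 == 5] = np.nan  # June always missing
        series = _series(values)
        with pytest.raises(ValueError, match="month 6"):
            compute_climatology(series, (1990, 1999))


class TestX11Decompose:
    def test_henderson_weights_reference_values(self):
        w = henderson_weights(13)
        assert w[6] == pytest.approx(0.24006, abs=5e-6)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, w[::-1])

    def test_linear_ramp_has_no_seasonal(self):
        b = 0.02
        series = _series(1.0 + b * np.arange(240))
        decomp = x11_decompose(series)
        assert np.max(np.abs(decomp.seasonal)) < 1e-6 * abs(b) * 240

    def test_ramp_plus_sinusoid_separated(self):
        n = 240
        t = np.arange(n)
        ramp = 0.5 + 0.01 * t
        sinus = 0.8 * np.sin(2 * np.pi * t / 12)
        decomp = x11_decompose(_series(ramp + sinus))
        core = decomp.core
        seasonal_core = slice(84, n - 84)
        assert np.allclose(
            decomp.seasonal[seasonal_core], sinus[seasonal_core], atol=0.01 * 0.8
        )
        assert np.allclose(decomp.trend[core], ramp[core], rtol=0.01)

    def test_additive_identity_exact(self, rng):
        x = rng.standard_normal(200)
        decomp = x11_decompose(_series(x))
        assert np.allclose(decomp.reconstruct(), x, atol=1e-12)

    def test_seasonal_sums_to_zero_away_from_endpoints(self):
        n = 300
        t = np.arange(n)
        x = 0.3 * np.cos(2 * np.pi * t / 12) + 0.002 * t
        decomp = x11_decompose(_series(x))
        # the seasonal component is filter-clean ~84 months in from each end
        sums = np.convolve(decomp.seasonal, np.ones(12), mode="valid")
        interior = sums[84 : n - 95]
        assert np.max(np.abs(interior)) < 1e-8

    def test_too_short_series_rejected(self):
        with pytest.raises(DecompositionError):
            x11_decompose(_series(np.zeros(24)))

    def test_gappy_series_rejected(self):
        values = np.random.default_rng(0).standard_normal(100)
        values[50] = np.nan
        with pytest.raises(DecompositionError):
            x11_decompose(_series(values))


class TestLinearTrend:
    def test_noiseless_line(self):
        t = 1990 + np.arange(120) / 12
        res = linear_trend(3.0 + 0.004 * t, t)
        assert res.gradient == pytest.approx(0.004, abs=1e-12)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)
        assert res.significant

    def test_constant_series_not_significant(self):
        t = 1990 + np.arange(60) / 12
        res = linear_trend(np.full(60, 2.0), t)
        assert res.gradient == 0.0
        assert not res.significant

    def test_degenerate_time_axis(self):
        with pytest.raises(ValueError):
            linear_trend(np.arange(5.0), np.ones(5))

    def test_type_one_error_rate_near_alpha(self, rng):
        t = np.arange(480) / 12.0
        hits = sum(
            linear_trend(rng.standard_normal(480), t).significant
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_confidence_interval_coverage(self, rng):
        slope = 0.004
        t = np.arange(480) / 12.0
        covered = 0
        for _ in range(500):
            y = slope * t + 0.3 * rng.standard_normal(480)
            res = linear_trend(y, t)
            covered += res.ci_low <= slope <= res.ci_high
        assert 0.93 <= covered / 500 <= 0.97


class TestTrendChain:
    def test_noiseless_gradient_recovery_exact(self, small_grid):
        truth = default_sst_trend_field(small_grid)
        field = gen_env_series(small_grid, truth, seed=1, freq="daily", sigma=0.0)
        layer = trend_map(field)
        assert np.nanmax(np.abs(layer.gradient - truth)) < 1e-10

    def test_all_constant_field_zero_insignificant(self, small_grid):
        field = gen_env_series(
            small_grid,
            np.zeros(small_grid.shape),
            seed=0,
            freq="monthly",
            seasonal_amplitude=0.0,
            sigma=0.0,
            start_year=1990,
            end_year=2010,
        )
        layer = trend_map(field, reference=(1993, 2008))
        assert np.allclose(layer.gradient, 0.0, atol=1e-12)
        assert not np.any(layer.significant == 1.0)

    def test_monthly_input_equals_daily_expansion(self, small_grid):
        # a pH-like monthly product must give the same answer as running
        # the monthly-means step on its trivial daily expansion
        truth = 0.5 * default_sst_trend_field(small_grid)
        monthly = gen_env_series(
            small_grid, truth, seed=5, freq="monthly", sigma=0.0,
            start_year=1990, end_year=2015,
        )
        nm = monthly.year.size
        daily_year = np.repeat(monthly.year, 30)
        daily_month = np.repeat(monthly.month, 30)
        daily_t = np.repeat(monthly.year + (monthly.month - 0.5) / 12, 30)
        daily_values = np.repeat(monthly.values, 30, axis=0)
        from sohotspots.trends import DailyField

        daily = DailyField(small_grid, daily_year, daily_month, daily_t, daily_values)
        a = trend_map(monthly)
        b = trend_map(daily)
        assert np.allclose(a.gradient, b.gradient, equal_nan=True, atol=1e-14)

    def test_reference_window_shift_leaves_gradient_unchanged(self):
        rng = np.random.default_rng(8)
        n = 480
        t = np.arange(n)
        x = 5 + 0.003 * t + 0.5 * np.sin(2 * np.pi * t / 12) + 0.1 * rng.standard_normal(n)
        series = _series(x, start=(1982, 1))
        a = trend_for_series(series, reference=(1993, 2014))
        b = trend_for_series(series, reference=(1985, 2000))
        assert a.gradient == pytest.approx(b.gradient, rel=1e-6)

    def test_gap_interpolation_tolerates_short_gaps(self):
        rng = np.random.default_rng(3)
        n = 480
        x = 2 + 0.004 * np.arange(n) / 12 + 0.1 * rng.standard_normal(n)
        x[100] = np.nan
        x[200:202] = np.nan
        series = _series(x, start=(1982, 1))
        res = trend_for_series(series)
        assert res.gradient == pytest.approx(0.004, rel=0.2)

    def test_long_gap_rejected(self):
        n = 480
        x = np.ones(n)
        x[200:210] = np.nan
        with pytest.raises(DecompositionError):
            trend_for_series(_series(x, start=(1982, 1)))

    def test_estimator_nearly_unbiased_on_ar1_series(self, rng):
        # mean bias over replicated seasonal+trend+AR(1) series < 5% of slope
        slope = 0.01
        n = 480
        t = np.arange(n)
        phi = 0.5
        estimates = []
        for _ in range(120):
            eps = 0.3 * rng.standard_normal(n)
            noise = np.empty(n)
            noise[0] = eps[0]
            for i in range(1, n):
                noise[i] = phi * noise[i - 1] + eps[i]
            x = slope * t / 12 + 0.8 * np.sin(2 * np.pi * t / 12) + noise
            estimates.append(trend_for_series(_series(x, start=(1982, 1))).gradient)
        bias = np.mean(estimates) - slope
        assert abs(bias) < 0.05 * slope
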