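"""1-5 rank scales: threshold fitting, application, trend-layer ranking."""

import numpy as np
import pytest
from scipy import stats

from sohotspots.grid import build_grid
from sohotspots.layers import TrendLayer, ValueLayer
from sohotspots.ranking import (
    DegenerateScaleError,
    RankScale,
    apply_ranks,
    fit_rank_scale,
    rank_trend_layer,
)


def _layer(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or build_grid(360.0 / values.shape[1], 45.0 / values.shape[0], -45.0)
    return ValueLayer(grid, values)


class TestFitRankScale:
    def test_even_spacing_identity(self):
        scale = fit_rank_scale(
            np.linspace(0, 5, 101),
            "identity",
            outlier_quantiles=(0.0, 1.0),
            zero_rule=False,  # keep the 0 endpoint so the range is [0, 5]
        )
        assert scale.thresholds == pytest.approx((1.0, 2.0, 3.0, 4.0))

    def test_two_values(self):
        scale = fit_rank_scale(
            np.array([10.0, 60.0]), "identity", outlier_quantiles=(0.0, 1.0)
        )
        assert scale.thresholds == pytest.approx((20.0, 30.0, 40.0, 50.0))

    def test_lognormal_with_quantile_clipping_matches_brute_force(self, rng):
        values = rng.lognormal(1.0, 1.5, 5000)
        scale = fit_rank_scale(values, "log", outlier_quantiles=(0.01, 0.99))
        logs = np.log(values)
        lo, hi = np.quantile(logs, [0.01, 0.99])
        expected = [lo + k * (hi - lo) / 5 for k in (1, 2, 3, 4)]
        assert scale.thresholds == pytest.approx(tuple(expected))

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateScaleError):
            fit_rank_scale(np.array([3.0, 3.0, 3.0]), "identity")

    def test_uneven_thresholds_rejected_by_invariant(self):
        with pytest.raises(ValueError):
            RankScale("identity", (1.0, 2.0, 3.5, 4.0), (0.0, 5.0))


class TestApplyRanks:
    def test_extremes_and_zero_rule(self):
        grid = build_grid(45.0, 15.0, -45.0)
        values = np.full(grid.shape, np.nan)
        values[0, :6] = [1.0, 100.0, 0.0, 0.5, 200.0, 50.0]
        layer = ValueLayer(grid, values)
        scale = fit_rank_scale(values, "log", outlier_quantiles=(0.0, 1.0))
        ranks = apply_ranks(layer, scale)
        # log range is [log 0.5, log 200]; thresholds every log(400)/5
        assert ranks.ranks[0, 0] == 1  # log 1 below the first threshold
        assert ranks.ranks[0, 3] == 1  # retained minimum
        assert ranks.ranks[0, 2] == 1  # zero rule, despite log transform
        assert ranks.ranks[0, 5] == 4  # log 50 in the fourth band
        assert ranks.ranks[0, 4] == 5  # retained maximum
        assert np.isnan(ranks.ranks[1, 0])  # missing stays missing

    def test_outlier_clipping_to_extreme_ranks(self):
        grid = build_grid(45.0, 15.0, -45.0)
        values = np.full(grid.shape, np.nan)
        values[0, :] = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 0.001, 1000.0]
        layer = ValueLayer(grid, values)
        scale = fit_rank_scale(values, "log", outlier_quantiles=(0.2, 0.8))
        ranks = apply_ranks(layer, scale)
        assert ranks.ranks[0, 6] == 1  # below the lower outlier bound
        assert ranks.ranks[0, 7] == 5  # above the upper outlier bound

    def test_negative_under_log_rejected(self):
        grid = build_grid(45.0, 15.0, -45.0)
        values = np.full(grid.shape, 1.0)
        values[0, 0] = -2.0
        scale = RankScale("log", (1.0, 2.0, 3.0, 4.0), (0.0, 5.0))
        with pytest.raises(ValueError):
            apply_ranks(ValueLayer(grid, values), scale)

    def test_brute_force_threshold_count_oracle(self, rng):
        grid = build_grid(9.0, 3.0, -45.0)
        values = rng.lognormal(0, 1, grid.shape)
        values[rng.random(grid.shape) < 0.1] = np.nan
        values[rng.random(grid.shape) < 0.1] = 0.0
        layer = ValueLayer(grid, values)
        scale = fit_rank_scale(values, "log")
        ranks = apply_ranks(layer, scale)
        for row in range(grid.n_rows):
            for col in range(grid.n_cols):
                v = values[row, col]
                if np.isnan(v):
                    assert np.isnan(ranks.ranks[row, col])
                elif v == 0:
                    assert ranks.ranks[row, col] == 1
                else:
                    expected = 1 + sum(np.log(v) >= t for t in scale.thresholds)
                    assert ranks.ranks[row, col] == expected

    def test_monotonicity(self, rng):
        values = np.sort(rng.lognormal(0, 1, 40))
        grid = build_grid(9.0, 45.0, -45.0)
        layer = ValueLayer(grid, values.reshape(1, 40))
        scale = fit_rank_scale(values, "log")
        ranks = apply_ranks(layer, scale).ranks.ravel()
        assert np.all(np.diff(ranks) >= 0)

    def test_rank_histogram_uniform_for_uniform_transformed_sample(self, rng):
        # uniform on the transformed retained range -> ~equal rank counts
        n = 100_000
        values = np.exp(rng.uniform(0.0, 5.0, n))
        scale = fit_rank_scale(values, "log", outlier_quantiles=(0.0, 1.0))
        t = np.log(values)
        ranks = 1 + np.searchsorted(np.asarray(scale.thresholds), t, side="right")
        counts = np.bincount(ranks, minlength=6)[1:6]
        chi2 = ((counts - n / 5) ** 2 / (n / 5)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_applying_ranks_twice_is_idempotent(self, rng):
        grid = build_grid(9.0, 3.0, -45.0)
        values = rng.lognormal(0, 1, grid.shape)
        layer = ValueLayer(grid, values)
        scale = fit_rank_scale(values, "log")
        first = apply_ranks(layer, scale)
        second = apply_ranks(layer, scale)
        assert np.array_equal(first.ranks, second.ranks, equal_nan=True)


def _trend_layer(gradient, significant, grid):
    shape = grid.shape
    grad = np.asarray(gradient, dtype=float)
    sig = np.asarray(significant, dtype=float)
    zeros = np.zeros(shape)
    p = np.where(sig == 1.0, 0.01, 0.5)
    p[np.isnan(grad)] = np.nan
    return TrendLayer(grid, grad, grad - 0.001, grad + 0.001, p, sig)


class TestRankTrendLayer:
    def test_all_insignificant_is_all_rank_one(self, small_grid):
        grad = np.full(small_grid.shape, 0.01)
        sig = np.zeros(small_grid.shape)
        ranks = rank_trend_layer(_trend_layer(grad, sig, small_grid), "warming")
        assert np.all(ranks.ranks == 1.0)

    def test_largest_significant_warming_gets_rank_five(self, small_grid, rng):
        grad = rng.uniform(0.001, 0.01, small_grid.shape)
        grad[2, 5] = 0.02  # unique maximum
        sig = np.ones(small_grid.shape)
        ranks = rank_trend_layer(_trend_layer(grad, sig, small_grid), "warming")
        assert ranks.ranks[2, 5] == 5.0

    def test_negative_or_insignificant_warming_rank_one(self, small_grid, rng):
        grad = rng.uniform(0.001, 0.01, small_grid.shape)
        sig = np.ones(small_grid.shape)
        grad[0, 0] = -0.005
        sig[0, 1] = 0.0
        ranks = rank_trend_layer(_trend_layer(grad, sig, small_grid), "warming")
        assert ranks.ranks[0, 0] == 1.0
        assert ranks.ranks[0, 1] == 1.0

    def test_acidification_ranks_magnitude_of_declines(self, small_grid, rng):
        grad = -rng.uniform(0.0019, 0.0025, small_grid.shape)
        grad[1, 3] = -0.004  # steepest decline
        grad[1, 4] = 0.001  # pH rising: low concern
        sig = np.ones(small_grid.shape)
        ranks = rank_trend_layer(
            _trend_layer(grad, sig, small_grid), "acidification"
        )
        assert ranks.ranks[1, 3] == 5.0
        assert ranks.ranks[1, 4] == 1.0

    def test_sqrt_threshold_oracle_on_positive_significant_subset(
        self, small_grid, rng
    ):
        grad = rng.uniform(-0.005, 0.015, small_grid.shape)
        sig = (rng.random(small_grid.shape) < 0.7).astype(float)
        layer = _trend_layer(grad, sig, small_grid)
        ranks = rank_trend_layer(layer, "warming")
        eligible = (sig == 1.0) & (grad > 0)
        scale = fit_rank_scale(
            grad[eligible], "sqrt", zero_rule=False
        )
        for row in range(small_grid.n_rows):
            for col in range(small_grid.n_cols):
                if eligible[row, col]:
                    expected = 1 + sum(
                        np.sqrt(grad[row, col]) >= t for t in scale.thresholds
                    )
                    assert ranks.ranks[row, col] == expected
                else:
                    assert ranks.ranks[row, col] == 1.0

    def test_missing_trend_cells_stay_missing(self, small_grid):
        grad = np.full(small_grid.shape, 0.01)
        sig = np.ones(small_grid.shape)
        grad[0, 0] = np.nan
        sig[0, 0] = np.nan
        ranks = rank_trend_layer(_trend_layer(grad, sig, small_grid), "warming")
        assert np.isnan(ranks.ranks[0, 0])
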