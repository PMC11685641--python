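"""Discrete 1-5 concern ranking of continuous layers.

Each layer is transformed to approximate normality (log for abundances and
person-day intensities, square root for positive SST trends, magnitude for
pH trends), zeros and outliers are omitted, and four thresholds are placed
at evenly spaced interior points of the retained range — each of the five
ranks then spans an equal transformed interval.  Zeros rank 1; values
outside the outlier bounds clip to rank 1 or 5; missing stays missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import RankLayer, TrendLayer, ValueLayer

TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "sqrt": np.sqrt,
    "negate": lambda x: -x,
}

#: Default quantile pair defining outliers on the transformed nonzero data.
DEFAULT_OUTLIER_QUANTILES = (0.01, 0.99)


class DegenerateScaleError(ValueError):
    """Too few distinct values to fit a ranking scale."""


@dataclass(frozen=True)
class RankScale:
    """A fitted 1-5 ranking rule on the transformed measurement scale."""

    transform: str
    thresholds: tuple[float, float, float, float]
    outlier_bounds: tuple[float, float]
    zero_rule: bool = True

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        th = np.asarray(self.thresholds, dtype=float)
        if th.shape != (4,) or not np.all(np.diff(th) > 0):
            raise ValueError("need exactly 4 strictly ascending thresholds")
        gaps = np.diff(np.r_[self.outlier_bounds[0], th, self.outlier_bounds[1]])
        if not np.allclose(gaps, gaps[0], rtol=0, atol=1e-9 * max(1.0, abs(gaps[0]))):
            raise ValueError("thresholds must be evenly spaced across the range")


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log" and np.any(values[~np.isnan(values)] < 0):
        raise ValueError("negative value under log transform")
    if transform == "sqrt" and np.any(values[~np.isnan(values)] < 0):
        raise ValueError("negative value under sqrt transform")
    with np.errstate(divide="ignore"):
        return TRANSFORMS[transform](values)


def fit_rank_scale(
    values,
    transform: str = "log",
    outlier_quantiles: tuple[float, float] = DEFAULT_OUTLIER_QUANTILES,
    zero_rule: bool = True,
) -> RankScale:
    """Fit the 1-5 scale to a layer's non-missing values.

    Zeros (when ``zero_rule``) and NaNs are omitted, the remaining values
    transformed, outlier bounds set at the given quantiles, and the four
    thresholds placed at ``lo + k (hi - lo)/5`` for k = 1..4.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[~np.isnan(arr)]
    if zero_rule:
        arr = arr[arr != 0]
    if arr.size < 2:
        raise DegenerateScaleError("need at least 2 nonzero values to fit a scale")
    t = _transform(arr, transform)
    lo, hi = np.quantile(t, outlier_quantiles)
    if not hi > lo:
        raise DegenerateScaleError(
            "degenerate transformed range after outlier clipping"
        )
    thresholds = tuple(lo + k * (hi - lo) / 5.0 for k in (1, 2, 3, 4))
    return RankScale(transform, thresholds, (float(lo), float(hi)), zero_rule)


def apply_ranks(layer: ValueLayer, scale: RankScale) -> RankLayer:
    """Rank every cell of a layer on a fitted scale.

    rank = 1 + number of thresholds at or below the transformed value (ties
    take the higher rank); zeros rank 1 under the zero rule; values outside
    the outlier bounds clip to rank 1 or 5; missing cells stay missing.
    """
    values = layer.values
    ranks = np.full(values.shape, np.nan)
    present = ~np.isnan(values)
    zero = present & (values == 0)
    if scale.zero_rule:
        ranks[zero] = 1.0
        todo = present & ~zero
    else:
        todo = present
    if todo.any():
        t = _transform(values[todo], scale.transform)
        r = 1 + np.searchsorted(np.asarray(scale.thresholds), t, side="right")
        ranks[todo] = r
    return RankLayer(layer.grid, ranks, scale)


def rank_layer(
    layer: ValueLayer,
    transform: str = "log",
    outlier_quantiles: tuple[float, float] = DEFAULT_OUTLIER_QUANTILES,
    zero_rule: bool = True,
) -> RankLayer:
    """Fit a scale on a layer and apply it (the common one-shot path)."""
    scale = fit_rank_scale(layer.values, transform, outlier_quantiles, zero_rule)
    return apply_ranks(layer, scale)


def rank_trend_layer(
    trends: TrendLayer,
    direction: str,
    outlier_quantiles: tuple[float, float] = DEFAULT_OUTLIER_QUANTILES,
) -> RankLayer:
    """Rank a trend layer by the magnitude of concerning rates of change.

    ``direction="warming"``: cells with significant positive gradients are
    ranked on a square-root scale fitted to those gradients; insignificant
    or negative cells are low concern (rank 1).  ``direction="acidification"``:
    magnitudes of significant negative gradients are ranked on an identity
    scale; insignificant or positive cells rank 1.  Missing cells stay
    missing.
    """
    if direction == "warming":
        eligible = (trends.significant == 1.0) & (trends.gradient > 0)
        magnitude = trends.gradient
        transform = "sqrt"
    elif direction == "acidification":
        eligible = (trends.significant == 1.0) & (trends.gradient < 0)
        magnitude = -trends.gradient
        transform = "identity"
    else:
        raise ValueError(f"unknown direction {direction!r}")

    present = trends.mask
    ranks = np.full(trends.gradient.shape, np.nan)
    ranks[present] = 1.0
    if eligible.any() and np.unique(magnitude[eligible]).size < 2:
        # a lone eligible value is the observed maximum: top concern
        ranks[eligible] = 5.0
        scale = None
    elif eligible.any():
        scale = fit_rank_scale(
            magnitude[eligible], transform, outlier_quantiles, zero_rule=False
        )
        t = _transform(magnitude[eligible], transform)
        ranks[eligible] = 1 + np.searchsorted(
            np.asarray(scale.thresholds), t, side="right"
        )
    else:
        scale = None
    return RankLayer(trends.grid, ranks, scale)
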