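"""Per-cell trend analysis of gridded environmental series.

The long-term rate of change of SST-like and pH-like fields is estimated
cell by cell with a five-step chain:

1. daily values are reduced to calendar-month means (skipped for inputs
   already provided monthly);
2. a per-calendar-month climatology is computed over a reference window
   (1993-2014 by default);
3. differencing the climatology from the monthly means gives anomalies;
4. anomalies are split into seasonal, trend and irregular components with a
   classical additive X11 core (centred 2x12 moving average, 3x3 and 3x5
   within-month seasonal smoothers, 13-term Henderson trend filter);
5. an ordinary least-squares line fitted to the trend component gives the
   gradient (units yr^-1), its 95% confidence interval and a two-sided
   t-test p-value; cells with p > 0.05 are flagged insignificant.

Moving-average endpoints are filled with truncated weights renormalised to
preserve level and slope (so linear series pass through every filter
unchanged), and the line in step 5 is fitted only on the "core" of the
series where every filter feeding the trend component is fully symmetric
(42 months in from each end); endpoint windows cannot separate seasonal
from trend exactly, and restricting the fit to the core makes the
noiseless limit exact.

The time coordinate used for the fit is nominal mid-month decimal years,
``year + (month - 0.5)/12``: monthly series are treated as uniformly spaced,
as is standard for climate trend fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec
from .layers import TrendLayer

#: Minimum consecutive non-missing months for an X11 decomposition.
MIN_MONTHS_DECOMP = 36
#: Months at each end of a series where the trend component is affected by
#: asymmetric endpoint filters; excluded from the trend fit.
X11_CORE_MARGIN = 42
#: Longest run of missing months bridged by linear interpolation.
MAX_GAP_MONTHS = 2

_W_2X12 = np.r_[1.0, np.full(11, 2.0), 1.0] / 24.0
_W_3X3 = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0
_W_3X5 = np.array([1.0, 2.0, 3.0, 3.0, 3.0, 2.0, 1.0]) / 15.0


class DecompositionError(ValueError):
    """Series too short or too gappy for seasonal decomposition."""


def henderson_weights(n_terms: int = 13) -> np.ndarray:
    """Symmetric Henderson trend-filter weights (closed form)."""
    if n_terms % 2 != 1 or n_terms < 5:
        raise ValueError("Henderson filter length must be odd and >= 5")
    m = n_terms // 2
    n = m + 2
    j = np.arange(-m, m + 1, dtype=float)
    num = (
        315.0
        * ((n - 1) ** 2 - j**2)
        * (n**2 - j**2)
        * ((n + 1) ** 2 - j**2)
        * (3 * n**2 - 16 - 11 * j**2)
    )
    den = (
        8.0
        * n
        * (n**2 - 1)
        * (4 * n**2 - 1)
        * (4 * n**2 - 9)
        * (4 * n**2 - 25)
    )
    return num / den


_HENDERSON_13 = henderson_weights(13)


# ---------------------------------------------------------------------------
# series containers


@dataclass
class MonthlySeries:
    """A single cell's consecutive monthly values (NaN = missing month)."""

    year: np.ndarray
    month: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=int)
        self.month = np.asarray(self.month, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.year.shape == self.month.shape == self.values.shape):
            raise ValueError("year/month/values must have equal length")
        key = self.year * 12 + (self.month - 1)
        if self.year.size > 1 and not np.all(np.diff(key) == 1):
            raise ValueError("months must be strictly consecutive")

    @property
    def t(self) -> np.ndarray:
        """Nominal mid-month time in decimal years."""
        return self.year + (self.month - 0.5) / 12.0

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Climatology:
    """Per-calendar-month means over a reference window."""

    month_means: np.ndarray
    reference: tuple[int, int]

    def __post_init__(self) -> None:
        self.month_means = np.asarray(self.month_means, dtype=float)
        if self.month_means.shape != (12,):
            raise ValueError("a climatology has exactly 12 monthly means")


@dataclass
class Decomposition:
    """Additive X11 split: seasonal + trend + irregular == input.

    ``core`` marks the index range where the trend component is free of
    endpoint-filter effects (the refined seasonal's clean region is
    narrower, ~84 months in from each end, because its dependency chain is
    one filter deeper).
    """

    seasonal: np.ndarray
    trend: np.ndarray
    irregular: np.ndarray
    core: slice

    def reconstruct(self) -> np.ndarray:
        return self.seasonal + self.trend + self.irregular


@dataclass
class TrendResult:
    """Slope of the fitted line with 95% CI and two-sided t-test."""

    gradient: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


@dataclass
class MonthlyField:
    """Gridded monthly series: values (n_months, n_rows, n_cols)."""

    grid: GridSpec
    year: np.ndarray
    month: np.ndarray
    values: np.ndarray

    def cell_series(self, col: int, row: int) -> MonthlySeries:
        return MonthlySeries(self.year, self.month, self.values[:, row, col])


@dataclass
class DailyField:
    """Gridded daily series: values (n_days, n_rows, n_cols).

    ``t`` is the decimal-year timestamp of each day (used only for monthly
    grouping diagnostics; the trend fit uses nominal monthly times).
    """

    grid: GridSpec
    year: np.ndarray
    month: np.ndarray
    t: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# step 1: monthly means


def to_monthly(daily: pd.DataFrame) -> MonthlySeries:
    """Calendar-month means of a single cell's dated daily values.

    ``daily`` needs either a ``date`` column (datetime-like) or integer
    ``year``/``month`` columns, plus ``value``.  Months inside the observed
    span with no data become NaN entries.
    """
    if "value" not in daily.columns:
        raise ValueError("daily table needs a 'value' column")
    if "year" in daily.columns and "month" in daily.columns:
        year = daily["year"].to_numpy(dtype=int)
        month = daily["month"].to_numpy(dtype=int)
    elif "date" in daily.columns:
        dates = pd.to_datetime(daily["date"])
        year = dates.dt.year.to_numpy()
        month = dates.dt.month.to_numpy()
    else:
        raise ValueError("daily table needs 'date' or 'year'+'month' columns")
    values = daily["value"].to_numpy(dtype=float)

    key = year * 12 + (month - 1)
    lo, hi = key.min(), key.max()
    sums = np.zeros(hi - lo + 1)
    counts = np.zeros(hi - lo + 1)
    np.add.at(sums, key - lo, values)
    np.add.at(counts, key - lo, 1.0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    all_key = np.arange(lo, hi + 1)
    return MonthlySeries(all_key // 12, all_key % 12 + 1, means)


def monthly_mean_field(daily: DailyField) -> MonthlyField:
    """Vectorised calendar-month means of a gridded daily field."""
    key = daily.year * 12 + (daily.month - 1)
    order = np.argsort(key, kind="stable")
    key = key[order]
    vals = daily.values[order]
    starts = np.flatnonzero(np.r_[True, np.diff(key) > 0])
    sums = np.add.reduceat(vals, starts, axis=0)
    counts = np.diff(np.r_[starts, key.size]).astype(float)
    means = sums / counts[:, None, None]
    ukey = key[starts]
    lo, hi = ukey.min(), ukey.max()
    full = np.full((hi - lo + 1,) + vals.shape[1:], np.nan)
    full[ukey - lo] = means
    all_key = np.arange(lo, hi + 1)
    return MonthlyField(daily.grid, all_key // 12, all_key % 12 + 1, full)


# ---------------------------------------------------------------------------
# steps 2-3: climatology and anomalies


def compute_climatology(
    series: MonthlySeries, reference: tuple[int, int] = (1993, 2014)
) -> Climatology:
    """Mean of each calendar month within the reference years (inclusive)."""
    y0, y1 = reference
    in_ref = (series.year >= y0) & (series.year <= y1)
    if not in_ref.any():
        raise ValueError(f"reference window {reference} does not overlap the series")
    means = np.full(12, np.nan)
    for m in range(1, 13):
        sel = in_ref & (series.month == m) & ~np.isnan(series.values)
        if not sel.any():
            raise ValueError(
                f"calendar month {m} has no data in reference window {reference}"
            )
        means[m - 1] = series.values[sel].mean()
    return Climatology(means, reference)


def anomalies(series: MonthlySeries, clim: Climatology) -> MonthlySeries:
    """Monthly values minus the climatology of their calendar month."""
    return MonthlySeries(
        series.year, series.month, series.values - clim.month_means[series.month - 1]
    )


# ---------------------------------------------------------------------------
# step 4: X11-style decomposition


def _renorm(w: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Renormalise truncated filter weights to preserve level and slope.

    Returns c = w * (alpha + beta d) with sum(c) = 1 and sum(c d) = 0,
    where d are the offsets from the evaluation point.  For a symmetric
    window this reduces to w / sum(w); for a truncated one it keeps linear
    series passing through the filter unchanged.
    """
    s0 = w.sum()
    s1 = w @ d
    s2 = w @ (d * d)
    det = s0 * s2 - s1 * s1
    if det == 0:  # degenerate (single-point window)
        return w / s0
    alpha = s2 / det
    beta = -s1 / det
    return w * (alpha + beta * d)


def _smooth(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Symmetric moving average; endpoints use truncated weights
    renormalised to reproduce linear series exactly."""
    n = x.size
    h = w.size // 2
    out = np.empty(n)
    if n >= w.size:
        out[h : n - h] = np.convolve(x, w[::-1], mode="valid")
        edge = h
    else:
        edge = n  # every point is an endpoint
    offsets = np.arange(-h, h + 1, dtype=float)
    for i in range(min(edge, n)):
        # left end: window [0, i+h] clipped to the series
        stop = min(i + h + 1, n)
        ww = _renorm(w[h - i : h - i + stop], offsets[h - i : h - i + stop])
        out[i] = x[:stop] @ ww
        # right end, mirrored
        j = n - 1 - i
        start = max(j - h, 0)
        ww = _renorm(
            w[h - (j - start) : h + i + 1], offsets[h - (j - start) : h + i + 1]
        )
        out[j] = x[start:] @ ww
    return out


def _smooth_within_month(x: np.ndarray, start_month: int, w: np.ndarray) -> np.ndarray:
    """Apply a moving average separately to each calendar month's subseries."""
    out = np.empty_like(x)
    months = (start_month - 1 + np.arange(x.size)) % 12
    for m in range(12):
        idx = np.flatnonzero(months == m)
        if idx.size:
            out[idx] = _smooth(x[idx], w)
    return out


def x11_decompose(anom: MonthlySeries) -> Decomposition:
    """Classical additive X11 core on a gap-free anomaly series.

    Requires at least ``MIN_MONTHS_DECOMP`` consecutive non-missing months.
    Returns components satisfying seasonal + trend + irregular == input
    exactly; ``core`` marks the index range free of endpoint effects.
    """
    x = anom.values
    if np.any(np.isnan(x)):
        raise DecompositionError("series contains missing months")
    n = x.size
    if n < MIN_MONTHS_DECOMP:
        raise DecompositionError(
            f"series has {n} months; decomposition needs >= {MIN_MONTHS_DECOMP}"
        )
    start_month = int(anom.month[0])

    # initial trend and detrended series
    t1 = _smooth(x, _W_2X12)
    d = x - t1
    # initial seasonal: 3x3 within each calendar month, centred by a 2x12 MA
    s_raw = _smooth_within_month(d, start_month, _W_3X3)
    s1 = s_raw - _smooth(s_raw, _W_2X12)
    # refined trend: Henderson-13 on the deseasonalised series
    trend = _smooth(x - s1, _HENDERSON_13)
    # refined seasonal: 3x5 within month on the detrended series, re-centred
    s2_raw = _smooth_within_month(x - trend, start_month, _W_3X5)
    seasonal = s2_raw - _smooth(s2_raw, _W_2X12)
    irregular = x - trend - seasonal
    core = slice(min(X11_CORE_MARGIN, n // 2), max(n - X11_CORE_MARGIN, n // 2))
    return Decomposition(seasonal, trend, irregular, core)


# ---------------------------------------------------------------------------
# step 5: linear trend


def linear_trend(values: np.ndarray, t_years: np.ndarray, alpha: float = 0.05) -> TrendResult:
    """OLS slope of ``values`` against time in decimal years.

    Returns the gradient with its two-sided (1 - alpha) t-interval and
    p-value; ``significant`` is ``p <= alpha``.
    """
    values = np.asarray(values, dtype=float)
    t_years = np.asarray(t_years, dtype=float)
    ok = ~np.isnan(values)
    values, t_years = values[ok], t_years[ok]
    if values.size < 3:
        raise ValueError("trend fit needs at least 3 points")
    if np.ptp(t_years) == 0:
        raise ValueError("degenerate time axis (all times equal)")
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = stats.linregress(t_years, values)
    dof = values.size - 2
    if fit.stderr == 0 or np.isnan(fit.pvalue):
        # perfect fit: the line is exact, so p is 0 unless the slope is too
        half = 0.0
        p = 1.0 if fit.slope == 0 else 0.0
    else:
        half = stats.t.ppf(1 - alpha / 2.0, dof) * fit.stderr
        p = float(fit.pvalue)
    return TrendResult(
        gradient=float(fit.slope),
        ci_low=float(fit.slope - half),
        ci_high=float(fit.slope + half),
        p_value=p,
        significant=bool(p <= alpha),
    )


# ---------------------------------------------------------------------------
# the full per-cell chain


def _fill_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs no longer than ``max_gap``."""
    x = values.copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    idx = np.arange(x.size)
    runs = _nan_runs(isnan)
    for s, e in runs:
        if s == 0 or e == x.size:
            continue  # leading/trailing gaps are not interpolated
        if e - s <= max_gap:
            x[s:e] = np.interp(idx[s:e], [s - 1, e], [x[s - 1], x[e]])
    return x


def _nan_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    s = None
    for i, flag in enumerate(isnan):
        if flag and s is None:
            s = i
        elif not flag and s is not None:
            runs.append((s, i))
            s = None
    if s is not None:
        runs.append((s, isnan.size))
    return runs


def _trim_edges(values: np.ndarray) -> tuple[int, int]:
    """(start, stop) excluding leading and trailing NaN spans."""
    ok = np.flatnonzero(~np.isnan(values))
    if ok.size == 0:
        return (0, 0)
    return (int(ok[0]), int(ok[-1]) + 1)


def trend_for_series(
    series: MonthlySeries,
    reference: tuple[int, int] = (1993, 2014),
    alpha: float = 0.05,
    fit_on: str = "trend",
) -> TrendResult:
    """Run steps 2-5 on one cell's monthly series.

    ``fit_on`` selects the series handed to the linear model: the X11
    ``"trend"`` component (default) or the ``"seasonally_adjusted"`` series
    (trend + irregular).
    """
    if fit_on not in ("trend", "seasonally_adjusted"):
        raise ValueError(f"unknown fit_on={fit_on!r}")
    clim = compute_climatology(series, reference)
    anom = anomalies(series, clim)
    filled = _fill_gaps(anom.values, MAX_GAP_MONTHS)
    s, e = _trim_edges(filled)
    if np.any(np.isnan(filled[s:e])):
        raise DecompositionError(
            f"series has interior gaps longer than {MAX_GAP_MONTHS} months"
        )
    need = 2 * X11_CORE_MARGIN + 3
    if e - s < need:
        raise DecompositionError(
            f"gap-free span is {e - s} months; trend fit needs >= {need}"
        )
    run = MonthlySeries(anom.year[s:e], anom.month[s:e], filled[s:e])
    decomp = x11_decompose(run)
    y = decomp.trend if fit_on == "trend" else decomp.trend + decomp.irregular
    core = decomp.core
    return linear_trend(y[core], run.t[core], alpha=alpha)


def trend_map(
    field: MonthlyField | DailyField,
    reference: tuple[int, int] = (1993, 2014),
    alpha: float = 0.05,
    fit_on: str = "trend",
) -> TrendLayer:
    """Apply the five-step trend chain to every grid cell.

    Daily fields are first reduced to monthly means; fields supplied monthly
    skip that step.  Cells whose series fail a precondition are left missing
    and the failure recorded in ``TrendLayer.errors``.
    """
    if isinstance(field, DailyField):
        field = monthly_mean_field(field)
    grid = field.grid
    shape = grid.shape
    gradient = np.full(shape, np.nan)
    ci_low = np.full(shape, np.nan)
    ci_high = np.full(shape, np.nan)
    p_value = np.full(shape, np.nan)
    significant = np.full(shape, np.nan)
    errors: list[str] = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            series_values = field.values[:, row, col]
            if np.all(np.isnan(series_values)):
                continue
            series = MonthlySeries(field.year, field.month, series_values)
            try:
                res = trend_for_series(series, reference, alpha, fit_on)
            except (ValueError, DecompositionError) as exc:
                errors.append(f"cell (col={col}, row={row}): {exc}")
                continue
            gradient[row, col] = res.gradient
            ci_low[row, col] = res.ci_low
            ci_high[row, col] = res.ci_high
            p_value[row, col] = res.p_value
            significant[row, col] = float(res.significant)
    return TrendLayer(grid, gradient, ci_low, ci_high, p_value, significant, errors)
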