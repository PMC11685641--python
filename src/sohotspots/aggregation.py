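"""Project point samples and fine rasters onto the grid.

Skewed, zero-inflated abundance data (krill net catches, chlorophyll) are
summarised per cell with a geometric mean that assimilates zeros following
Habib (2012): for n observations of which n_pos are positive,

    G = (n_pos / n) * exp( mean(log(positive values)) )

so an all-positive sample reduces to the ordinary geometric mean, an
all-zero sample to 0, and zeros discount the positive-part geometric mean by
the observed frequency of presence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec, assign_cells
from .layers import ValueLayer

logger = logging.getLogger(__name__)

#: Months used for the biota layers (austral summer, when most krill net
#: samples were collected).
SUMMER_MONTHS = frozenset({1, 2, 3})


def geometric_mean_with_zeros(values) -> float:
    """Zero-assimilating geometric mean of a nonnegative sample.

    Raises ValueError on an empty sample or any negative value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty sample is undefined")
    if np.any(np.isnan(arr)):
        raise ValueError("sample contains NaN")
    if np.any(arr < 0):
        raise ValueError("geometric mean requires nonnegative values")
    pos = arr[arr > 0]
    if pos.size == 0:
        return 0.0
    return float(pos.size / arr.size * np.exp(np.mean(np.log(pos))))


def grid_point_samples(
    samples: pd.DataFrame,
    grid: GridSpec,
    month_filter: frozenset[int] | set[int] | None = SUMMER_MONTHS,
) -> ValueLayer:
    """Grid a (lon, lat, date, value) sample table by zero-assimilating
    geometric means.

    ``samples`` needs columns lon, lat, date (datetime-like or parseable) and
    value (nonnegative).  Rows outside ``month_filter`` are dropped first;
    cells receiving no samples are missing.
    """
    required = {"lon", "lat", "date", "value"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if np.any(samples["value"].to_numpy(dtype=float) < 0):
        raise ValueError("sample values must be nonnegative")

    dates = pd.to_datetime(samples["date"])
    if month_filter is not None:
        keep = dates.dt.month.isin(sorted(month_filter)).to_numpy()
    else:
        keep = np.ones(len(samples), dtype=bool)

    values = np.full(grid.shape, np.nan)
    counts = np.zeros(grid.shape, dtype=int)
    if not keep.any():
        logger.warning(
            "no samples survive the month filter %s; layer is fully missing",
            sorted(month_filter) if month_filter else None,
        )
        return ValueLayer(grid, values, counts)

    sub = samples.loc[keep]
    col, row, inside = assign_cells(
        sub["lon"].to_numpy(dtype=float), sub["lat"].to_numpy(dtype=float), grid
    )
    col, row = col[inside], row[inside]
    vals = sub["value"].to_numpy(dtype=float)[inside]

    flat = row * grid.n_cols + col
    order = np.argsort(flat, kind="stable")
    flat, vals = flat[order], vals[order]
    starts = np.flatnonzero(np.r_[True, np.diff(flat) > 0])
    for s, e in zip(starts, np.r_[starts[1:], flat.size]):
        r, c = divmod(int(flat[s]), grid.n_cols)
        values[r, c] = geometric_mean_with_zeros(vals[s:e])
        counts[r, c] = e - s
    return ValueLayer(grid, values, counts)


def regrid_raster_geomean(fine: xr.DataArray, grid: GridSpec) -> ValueLayer:
    """Aggregate a fine lon/lat raster onto the grid by zero-assimilating
    geometric means of the fine-cell values whose centres fall in each cell.

    ``fine`` must have 1-D coordinates named lon and lat (cell centres) with
    spacing strictly finer than the target grid; NaNs are excluded before
    averaging.
    """
    if "lon" not in fine.dims or "lat" not in fine.dims:
        raise ValueError("fine raster must have lon and lat dimensions")
    lon = fine["lon"].to_numpy()
    lat = fine["lat"].to_numpy()
    if lon.size > 1 and abs(lon[1] - lon[0]) >= grid.lon_width:
        raise ValueError("fine raster lon spacing is not finer than the grid")
    if lat.size > 1 and abs(lat[1] - lat[0]) >= grid.lat_width:
        raise ValueError("fine raster lat spacing is not finer than the grid")

    data = fine.transpose("lat", "lon").to_numpy().astype(float)
    lon2, lat2 = np.meshgrid(lon, lat)
    col, row, inside = assign_cells(lon2.ravel(), lat2.ravel(), grid)
    vals = data.ravel()
    ok = inside & ~np.isnan(vals)
    col, row, vals = col[ok], row[ok], vals[ok]

    values = np.full(grid.shape, np.nan)
    counts = np.zeros(grid.shape, dtype=int)
    flat = row * grid.n_cols + col
    order = np.argsort(flat, kind="stable")
    flat, vals = flat[order], vals[order]
    if flat.size:
        starts = np.flatnonzero(np.r_[True, np.diff(flat) > 0])
        # vectorised Habib mean per group: count, positive count, log-sum
        ends = np.r_[starts[1:], flat.size]
        n = ends - starts
        pos = vals > 0
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.where(pos, vals, 1.0)), 0.0)
        cum_pos = np.r_[0, np.cumsum(pos)]
        cum_log = np.r_[0.0, np.cumsum(logs)]
        n_pos = cum_pos[ends] - cum_pos[starts]
        log_sum = cum_log[ends] - cum_log[starts]
        g = np.zeros(starts.size)
        nz = n_pos > 0
        g[nz] = n_pos[nz] / n[nz] * np.exp(log_sum[nz] / n_pos[nz])
        r, c = np.divmod(flat[starts], grid.n_cols)
        values[r, c] = g
        counts[r, c] = n
    return ValueLayer(grid, values, counts)
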