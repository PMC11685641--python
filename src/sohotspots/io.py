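"""Readers and writers for the pipeline's file formats.

Tabular inputs are CSV (krill samples, ship records, facility catalogue),
gridded data are CF-style NetCDF (written with xarray's scipy backend,
NETCDF3_CLASSIC), map exports are GeoJSON cell polygons, and configuration
and run reports are YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import GridSpec, cell_areas
from .human_activity import Facility, facilities_from_frame
from .layers import RankLayer, RiskMap, TrendLayer, ValueLayer
from .ranking import RankScale
from .trends import MonthlyField


class InputValidationError(ValueError):
    """Input file fails schema or value validation."""


# ---------------------------------------------------------------------------
# tabular inputs


def read_point_samples(path: str | Path) -> pd.DataFrame:
    """Read a (lon, lat, date, value) sample CSV with row-level validation."""
    frame = pd.read_csv(path)
    _require_columns(frame, {"lon", "lat", "date", "value"}, path)
    problems = []
    values = pd.to_numeric(frame["value"], errors="coerce")
    for idx in frame.index[values.isna() | (values < 0)]:
        # +2: 1-based line numbers plus the header line
        problems.append(f"line {idx + 2}: value must be a nonnegative number")
    lon = pd.to_numeric(frame["lon"], errors="coerce")
    lat = pd.to_numeric(frame["lat"], errors="coerce")
    bad_coord = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    for idx in frame.index[bad_coord]:
        problems.append(f"line {idx + 2}: invalid lon/lat")
    dates = pd.to_datetime(frame["date"], errors="coerce")
    for idx in frame.index[dates.isna()]:
        problems.append(f"line {idx + 2}: unparseable date")
    if problems:
        raise InputValidationError(f"{path}: " + "; ".join(problems[:20]))
    frame["date"] = dates
    return frame


def read_facilities(path: str | Path) -> list[Facility]:
    """Read a COMNAP-like facility catalogue CSV."""
    frame = pd.read_csv(path)
    _require_columns(
        frame,
        {"name", "lon", "lat", "facility_type", "seasonality", "peak_population"},
        path,
    )
    problems = []
    pops = pd.to_numeric(frame["peak_population"], errors="coerce")
    for idx in frame.index[pops.isna() | (pops < 0)]:
        problems.append(f"line {idx + 2}: peak_population must be >= 0")
    bad_season = ~frame["seasonality"].isin(["year-round", "seasonal"])
    for idx in frame.index[bad_season]:
        problems.append(
            f"line {idx + 2}: seasonality must be 'year-round' or 'seasonal'"
        )
    if problems:
        raise InputValidationError(f"{path}: " + "; ".join(problems[:20]))
    return facilities_from_frame(frame)


def read_ship_records(path: str | Path) -> pd.DataFrame:
    """Read an AIS-derived ship-day record CSV."""
    frame = pd.read_csv(path)
    _require_columns(frame, {"vessel_id", "vessel_type", "year", "days"}, path)
    if not ({"lon", "lat"} <= set(frame.columns) or {"col", "row"} <= set(frame.columns)):
        raise InputValidationError(
            f"{path}: ship records need lon/lat or col/row columns"
        )
    problems = []
    days = pd.to_numeric(frame["days"], errors="coerce")
    for idx in frame.index[days.isna() | (days < 0)]:
        problems.append(f"line {idx + 2}: days must be >= 0")
    if problems:
        raise InputValidationError(f"{path}: " + "; ".join(problems[:20]))
    return frame


def _require_columns(frame: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(frame.columns)
    if missing:
        raise InputValidationError(f"{path}: missing columns {sorted(missing)}")


# ---------------------------------------------------------------------------
# gridded NetCDF


def _grid_coords(grid: GridSpec) -> dict:
    lons, lats = grid.centroids()
    return {"lat": ("row", lats), "lon": ("col", lons)}


def _grid_attrs(grid: GridSpec) -> dict:
    return {
        "lon_width": grid.lon_width,
        "lat_width": grid.lat_width,
        "lat_north": grid.lat_north,
        "lat_south": grid.lat_south,
    }


def _grid_from_attrs(attrs: dict) -> GridSpec:
    return GridSpec(
        lon_width=float(attrs["lon_width"]),
        lat_width=float(attrs["lat_width"]),
        lat_north=float(attrs["lat_north"]),
        lat_south=float(attrs["lat_south"]),
    )


def write_value_layer(layer: ValueLayer, path: str | Path, name: str = "value") -> None:
    ds = xr.Dataset(
        {
            name: (("row", "col"), layer.values),
            "n_obs": (("row", "col"), layer.n_obs.astype(np.int32)),
        },
        coords=_grid_coords(layer.grid),
        attrs=_grid_attrs(layer.grid),
    )
    ds.to_netcdf(path, engine="scipy")


def read_value_layer(path: str | Path, name: str = "value") -> ValueLayer:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs)
    return ValueLayer(grid, ds[name].to_numpy(), ds["n_obs"].to_numpy().astype(int))


def write_rank_layer(layer: RankLayer, path: str | Path) -> None:
    attrs = _grid_attrs(layer.grid)
    if layer.scale is not None:
        attrs["scale"] = json.dumps(rank_scale_to_dict(layer.scale))
    ds = xr.Dataset(
        {"rank": (("row", "col"), layer.ranks)},
        coords=_grid_coords(layer.grid),
        attrs=attrs,
    )
    ds.to_netcdf(path, engine="scipy")


def read_rank_layer(path: str | Path) -> RankLayer:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs)
    scale = None
    if "scale" in ds.attrs:
        scale = rank_scale_from_dict(json.loads(ds.attrs["scale"]))
    return RankLayer(grid, ds["rank"].to_numpy(), scale)


def write_trend_layer(layer: TrendLayer, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "gradient": (("row", "col"), layer.gradient),
            "ci_low": (("row", "col"), layer.ci_low),
            "ci_high": (("row", "col"), layer.ci_high),
            "p_value": (("row", "col"), layer.p_value),
            "significant": (("row", "col"), layer.significant),
        },
        coords=_grid_coords(layer.grid),
        attrs=_grid_attrs(layer.grid),
    )
    ds.to_netcdf(path, engine="scipy")


def read_trend_layer(path: str | Path) -> TrendLayer:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs)
    return TrendLayer(
        grid,
        ds["gradient"].to_numpy(),
        ds["ci_low"].to_numpy(),
        ds["ci_high"].to_numpy(),
        ds["p_value"].to_numpy(),
        ds["significant"].to_numpy(),
    )


def write_risk_map(risk: RiskMap, path: str | Path) -> None:
    attrs = _grid_attrs(risk.grid)
    attrs["provenance"] = json.dumps(risk.provenance)
    ds = xr.Dataset(
        {"score": (("row", "col"), risk.scores)},
        coords=_grid_coords(risk.grid),
        attrs=attrs,
    )
    ds.to_netcdf(path, engine="scipy")


def read_risk_map(path: str | Path) -> RiskMap:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs)
    return RiskMap(grid, ds["score"].to_numpy(), json.loads(ds.attrs["provenance"]))


def write_monthly_field(
    field_: MonthlyField, path: str | Path, name: str = "value"
) -> None:
    ds = xr.Dataset(
        {name: (("time", "row", "col"), field_.values)},
        coords={
            "year": ("time", field_.year.astype(np.int32)),
            "month": ("time", field_.month.astype(np.int32)),
            **_grid_coords(field_.grid),
        },
        attrs=_grid_attrs(field_.grid),
    )
    ds.to_netcdf(path, engine="scipy")


def read_monthly_field(path: str | Path, name: str = "value") -> MonthlyField:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs)
    return MonthlyField(
        grid,
        ds["year"].to_numpy().astype(int),
        ds["month"].to_numpy().astype(int),
        ds[name].to_numpy(),
    )


def write_fine_raster(raster: xr.DataArray, path: str | Path) -> None:
    raster.to_dataset(name=raster.name or "value").to_netcdf(path, engine="scipy")


def read_fine_raster(path: str | Path, name: str = "chlorophyll") -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    return ds[name]


# ---------------------------------------------------------------------------
# GeoJSON export


def layer_to_geojson(
    grid: GridSpec, values: np.ndarray, value_name: str = "value", **extra_fields
) -> dict:
    """One rectangular polygon per non-missing cell, value as a property."""
    areas = cell_areas(grid)
    features = []
    for col, row in grid.cells():
        v = values[row, col]
        if np.isnan(v):
            continue
        lon_lo, lon_hi = grid.lon_bounds(col)
        lat_lo, lat_hi = grid.lat_bounds(row)
        ring = [
            [lon_lo, lat_lo],
            [lon_hi, lat_lo],
            [lon_hi, lat_hi],
            [lon_lo, lat_hi],
            [lon_lo, lat_lo],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "col": col,
                    "row": row,
                    "area_km2": float(areas[row, col]),
                    value_name: float(v),
                    **extra_fields,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# configuration and run report


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serialisable to YAML."""

    # grid
    lon_width: float = 9.0
    lat_width: float = 3.0
    lat_north: float = -45.0
    lat_south: float = -90.0
    # analysis settings
    month_filter: list[int] = field(default_factory=lambda: [1, 2, 3])
    climatology_reference: list[int] = field(default_factory=lambda: [1993, 2014])
    significance_alpha: float = 0.05
    trend_fit_on: str = "trend"
    outlier_quantiles: list[float] = field(default_factory=lambda: [0.01, 0.99])
    ship_mask_lat: float | None = -60.0
    facility_seasonal_weighting: bool = False
    facility_remote_decay: str = "inverse_square"
    persons_aboard: dict[str, float] = field(
        default_factory=lambda: {
            "fishing": 40.0,
            "tourist": 250.0,
            "cargo/supply": 30.0,
            "research": 60.0,
            "other": 25.0,
        }
    )
    # inputs: either synthesize, or read from paths
    synthesize: bool = True
    seed: int = 0
    sst_freq: str = "daily"
    input_paths: dict[str, str] = field(default_factory=dict)
    # outputs
    output_dir: str = "sohotspots-output"

    def grid(self) -> GridSpec:
        return GridSpec(
            lon_width=self.lon_width,
            lat_width=self.lat_width,
            lat_north=self.lat_north,
            lat_south=self.lat_south,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def rank_scale_to_dict(scale: RankScale) -> dict:
    return {
        "transform": scale.transform,
        "thresholds": [float(t) for t in scale.thresholds],
        "outlier_bounds": [float(b) for b in scale.outlier_bounds],
        "zero_rule": bool(scale.zero_rule),
    }


def rank_scale_from_dict(data: dict) -> RankScale:
    return RankScale(
        transform=data["transform"],
        thresholds=tuple(data["thresholds"]),
        outlier_bounds=tuple(data["outlier_bounds"]),
        zero_rule=data["zero_rule"],
    )


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
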