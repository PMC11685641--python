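"""Circumpolar longitude-latitude grid shared by every data layer.

All layers in the risk-mapping pipeline are projected onto one coarse
longitude-latitude grid (9° x 3° by default, spanning the Southern Ocean
from the pole to 45°S).  Cells are addressed by a 0-based (col, row) pair:
columns count eastward from -180°, rows count northward from the southern
limit.  Bins are half-open [lo, hi) on both axes, with +180° wrapping onto
the -180° column, so every in-range coordinate belongs to exactly one cell.

Cell areas use the spherical-zone formula on an authalic sphere
(R = 6371.0072 km): A = R^2 * dlon_rad * (sin(lat_hi) - sin(lat_lo)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

#: Authalic Earth radius in km (sphere with the same surface area as the
#: WGS84 ellipsoid).  The analysis reports densities per 10,000 km^2 without
#: naming an Earth model, so a single authalic sphere is used throughout.
EARTH_RADIUS_KM = 6371.0072


class GridConfigError(ValueError):
    """Grid parameters that do not tile the domain."""


@dataclass(frozen=True)
class GridSpec:
    """A regular lon-lat grid covering [lat_south, lat_north) x [-180, 180).

    Parameters
    ----------
    lon_width, lat_width:
        Cell dimensions in degrees.  360 must be an integer multiple of
        ``lon_width`` and the latitude span an integer multiple of
        ``lat_width``.
    lat_north, lat_south:
        Northern and southern domain limits in degrees.
    """

    lon_width: float = 9.0
    lat_width: float = 3.0
    lat_north: float = -45.0
    lat_south: float = -90.0

    def __post_init__(self) -> None:
        if not _divides(360.0, self.lon_width):
            raise GridConfigError(
                f"lon_width={self.lon_width} does not divide 360 degrees"
            )
        span = self.lat_north - self.lat_south
        if span <= 0:
            raise GridConfigError(
                f"lat_north={self.lat_north} must exceed lat_south={self.lat_south}"
            )
        if not _divides(span, self.lat_width):
            raise GridConfigError(
                f"lat_width={self.lat_width} does not divide the "
                f"latitude span {span} degrees"
            )

    @property
    def n_cols(self) -> int:
        return round(360.0 / self.lon_width)

    @property
    def n_rows(self) -> int:
        return round((self.lat_north - self.lat_south) / self.lat_width)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) — the layout of every per-cell array."""
        return (self.n_rows, self.n_cols)

    # -- geometry ---------------------------------------------------------

    def lon_bounds(self, col: int) -> tuple[float, float]:
        lo = -180.0 + col * self.lon_width
        return (lo, lo + self.lon_width)

    def lat_bounds(self, row: int) -> tuple[float, float]:
        lo = self.lat_south + row * self.lat_width
        return (lo, lo + self.lat_width)

    def centroid(self, col: int, row: int) -> tuple[float, float]:
        """Cell midpoint as (lon, lat) in degrees."""
        lon_lo, lon_hi = self.lon_bounds(col)
        lat_lo, lat_hi = self.lat_bounds(row)
        return ((lon_lo + lon_hi) / 2.0, (lat_lo + lat_hi) / 2.0)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of centroid longitudes (n_cols,) and latitudes (n_rows,)."""
        lons = -180.0 + (np.arange(self.n_cols) + 0.5) * self.lon_width
        lats = self.lat_south + (np.arange(self.n_rows) + 0.5) * self.lat_width
        return lons, lats

    def cells(self) -> Iterator[tuple[int, int]]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield (col, row)


def build_grid(
    lon_width: float = 9.0,
    lat_width: float = 3.0,
    lat_north: float = -45.0,
    lat_south: float = -90.0,
) -> GridSpec:
    """Construct a :class:`GridSpec`; defaults give the 9°x3° grid to 45°S."""
    return GridSpec(
        lon_width=lon_width,
        lat_width=lat_width,
        lat_north=lat_north,
        lat_south=lat_south,
    )


def assign_cell(lon: float, lat: float, grid: GridSpec) -> tuple[int, int] | None:
    """Map a (lon, lat) coordinate to its (col, row) cell, or None.

    Longitude +180 wraps onto the -180 column.  Latitudes at or north of
    ``grid.lat_north`` (and south of ``grid.lat_south``) fall outside the
    domain and return None.  Coordinates outside [-180, 180] x [-90, 90]
    raise ValueError.
    """
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise ValueError(f"coordinate ({lon}, {lat}) outside valid lon/lat range")
    if lat < grid.lat_south or lat >= grid.lat_north:
        return None
    if lon == 180.0:
        lon = -180.0
    col = int((lon + 180.0) // grid.lon_width)
    row = int((lat - grid.lat_south) // grid.lat_width)
    col = min(col, grid.n_cols - 1)
    row = min(row, grid.n_rows - 1)
    return (col, row)


def assign_cells(
    lon: np.ndarray, lat: np.ndarray, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`assign_cell`.

    Returns (col, row, inside) integer arrays; entries with ``inside`` False
    (north of the domain) carry undefined col/row.  Out-of-range coordinates
    raise ValueError.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any((lon < -180.0) | (lon > 180.0) | (lat < -90.0) | (lat > 90.0)):
        raise ValueError("coordinates outside valid lon/lat range")
    lon = np.where(lon == 180.0, -180.0, lon)
    inside = (lat >= grid.lat_south) & (lat < grid.lat_north)
    col = np.clip(
        np.floor((lon + 180.0) / grid.lon_width).astype(int), 0, grid.n_cols - 1
    )
    row = np.clip(
        np.floor((lat - grid.lat_south) / grid.lat_width).astype(int),
        0,
        grid.n_rows - 1,
    )
    return col, row, inside


def cell_area(
    col: int, row: int, grid: GridSpec, earth_radius: float = EARTH_RADIUS_KM
) -> float:
    """Spherical area of one cell in km^2."""
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        raise IndexError(f"cell ({col}, {row}) outside grid {grid.shape}")
    lat_lo, lat_hi = grid.lat_bounds(row)
    dlon = math.radians(grid.lon_width)
    return (
        earth_radius**2
        * dlon
        * (math.sin(math.radians(lat_hi)) - math.sin(math.radians(lat_lo)))
    )


def cell_areas(grid: GridSpec, earth_radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """(n_rows, n_cols) array of cell areas in km^2 (constant along rows)."""
    lat_lo = grid.lat_south + np.arange(grid.n_rows) * grid.lat_width
    lat_hi = lat_lo + grid.lat_width
    dlon = np.radians(grid.lon_width)
    band = earth_radius**2 * dlon * (np.sin(np.radians(lat_hi)) - np.sin(np.radians(lat_lo)))
    return np.repeat(band[:, None], grid.n_cols, axis=1)


def great_circle_km(
    lon1: float | np.ndarray,
    lat1: float | np.ndarray,
    lon2: float | np.ndarray,
    lat2: float | np.ndarray,
    earth_radius: float = EARTH_RADIUS_KM,
) -> np.ndarray:
    """Haversine great-circle distance in km on the authalic sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * earth_radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def grid_to_geojson(grid: GridSpec) -> dict:
    """GeoJSON FeatureCollection: one rectangular polygon per cell with
    col/row/area_km2 properties."""
    features = []
    areas = cell_areas(grid)
    for col, row in grid.cells():
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
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _divides(total: float, width: float) -> bool:
    if width <= 0:
        return False
    ratio = total / width
    return abs(ratio - round(ratio)) < 1e-9
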