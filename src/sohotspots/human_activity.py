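"""Human-activity proxies for local microplastic emission.

Two emission proxies share the person-day currency:

* ship traffic — per-vessel cell-year ship-days are converted to person-days
  by the typical crew/passenger complement of the vessel type, summed within
  the five vessel types, and averaged across years;
* terrestrial facilities — a year-round facility with peak population p
  contributes 365 p person-days per year, a seasonal one (operating six
  months) 182.5 p.

Facility influence is spread over the ocean as an effective population
density (people per 10,000 km^2): a cell containing facilities takes the
housed population divided by the cell area, while every other cell receives
p / (pi d^2) from each facility at great-circle distance d km — population
smeared uniformly over the disc whose radius is that distance, an
inverse-square decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, assign_cell, assign_cells, cell_areas, great_circle_km
from .layers import ValueLayer

VESSEL_TYPES = ("fishing", "tourist", "cargo/supply", "research", "other")

FACILITY_TYPES = (
    "research station",
    "camp",
    "airfield camp",
    "refuge",
    "depot",
    "laboratory",
)

#: Facility population-size categories (lower bounds; upper bound open).
POPULATION_CATEGORY_EDGES = (0, 10, 25, 50, 100)
POPULATION_CATEGORY_LABELS = ("0-9", "10-24", "25-49", "50-99", ">=100")

DAYS_YEAR_ROUND = 365.0
DAYS_SEASONAL = 182.5


@dataclass(frozen=True)
class Facility:
    name: str
    lon: float
    lat: float
    facility_type: str
    seasonality: str  # "year-round" or "seasonal"
    peak_population: int

    def __post_init__(self) -> None:
        if self.peak_population < 0:
            raise ValueError(f"facility {self.name}: negative peak population")
        if self.seasonality not in ("year-round", "seasonal"):
            raise ValueError(
                f"facility {self.name}: unknown seasonality {self.seasonality!r}"
            )


def population_category(peak_population: int) -> str:
    """Label of the five-way facility population-size grouping."""
    idx = int(np.searchsorted(POPULATION_CATEGORY_EDGES, peak_population, side="right")) - 1
    return POPULATION_CATEGORY_LABELS[idx]


def annual_person_days(facility: Facility) -> float:
    """Person-days per year housed by a facility: 365 p or 182.5 p."""
    if facility.seasonality == "year-round":
        return DAYS_YEAR_ROUND * facility.peak_population
    if facility.seasonality == "seasonal":
        return DAYS_SEASONAL * facility.peak_population
    raise ValueError(f"unknown seasonality {facility.seasonality!r}")


def seasonally_weighted_population(facility: Facility) -> float:
    """Annual-equivalent population: p year-round, p/2 seasonal."""
    if facility.seasonality == "year-round":
        return float(facility.peak_population)
    if facility.seasonality == "seasonal":
        return facility.peak_population * (DAYS_SEASONAL / DAYS_YEAR_ROUND)
    raise ValueError(f"unknown seasonality {facility.seasonality!r}")


def facilities_from_frame(frame: pd.DataFrame) -> list[Facility]:
    """Build Facility records from a COMNAP-like catalogue table."""
    required = {"name", "lon", "lat", "facility_type", "seasonality", "peak_population"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"facility catalogue missing columns: {sorted(missing)}")
    return [
        Facility(
            name=str(r.name_),
            lon=float(r.lon),
            lat=float(r.lat),
            facility_type=str(r.facility_type),
            seasonality=str(r.seasonality),
            peak_population=int(r.peak_population),
        )
        for r in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def ship_person_days(
    records: pd.DataFrame,
    persons_aboard: dict[str, float],
    grid: GridSpec,
    n_years: int | None = None,
) -> tuple[dict[str, ValueLayer], ValueLayer]:
    """Interannual-mean person-days per cell, by vessel type and in total.

    ``records`` needs columns vessel_id, vessel_type, year, days and either
    lon/lat or col/row.  Each record's days are multiplied by the
    persons-aboard entry for its type, summed per (cell, type, year), and
    averaged over the years (``n_years`` defaults to the number of distinct
    years present).  Returns ({type: layer}, total layer); cells with no
    traffic hold 0, so the layers have full coverage like the AIS product.
    """
    required = {"vessel_id", "vessel_type", "year", "days"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"ship record table missing columns: {sorted(missing)}")
    unknown = set(records["vessel_type"].unique()) - set(persons_aboard)
    if unknown:
        raise ValueError(
            f"persons-aboard table missing vessel types: {sorted(unknown)}"
        )
    if {"col", "row"} <= set(records.columns):
        col = records["col"].to_numpy(dtype=int)
        row = records["row"].to_numpy(dtype=int)
        inside = np.ones(len(records), dtype=bool)
    else:
        col, row, inside = assign_cells(
            records["lon"].to_numpy(dtype=float),
            records["lat"].to_numpy(dtype=float),
            grid,
        )
    if n_years is None:
        n_years = records["year"].nunique()
    persons = records["vessel_type"].map(persons_aboard).to_numpy(dtype=float)
    pdays = records["days"].to_numpy(dtype=float) * persons

    per_type: dict[str, ValueLayer] = {}
    total = np.zeros(grid.shape)
    types = records["vessel_type"].to_numpy()
    for vtype in VESSEL_TYPES:
        acc = np.zeros(grid.shape)
        sel = (types == vtype) & inside
        np.add.at(acc, (row[sel], col[sel]), pdays[sel])
        acc /= n_years
        per_type[vtype] = ValueLayer(grid, acc)
        total += acc
    return per_type, ValueLayer(grid, total)


def effective_population_density(
    facilities: list[Facility],
    grid: GridSpec,
    seasonal_weighting: bool = False,
    remote_decay: str = "inverse_square",
) -> ValueLayer:
    """Facility population smoothed over the grid, per 10,000 km^2.

    A cell containing facilities takes the total housed population divided
    by the cell area.  Every other cell sums, over all facilities, the
    population spread uniformly on the disc reaching the cell centroid:
    p / (pi d^2) with d the great-circle distance in km
    (``remote_decay="inverse_square"``, default).  The alternative
    ``"disc_ratio"`` reading multiplies that disc density by the ratio of
    cell area to disc area, an inverse-fourth-power decay.

    With ``seasonal_weighting`` the population p of seasonal facilities is
    halved (their annual person-day ratio) before smoothing.
    """
    if remote_decay not in ("inverse_square", "disc_ratio"):
        raise ValueError(f"unknown remote_decay={remote_decay!r}")
    values = np.zeros(grid.shape)
    if not facilities:
        return ValueLayer(grid, values)
    areas = cell_areas(grid)
    lons, lats = grid.centroids()
    lon2, lat2 = np.meshgrid(lons, lats)

    for fac in facilities:
        pop = (
            seasonally_weighted_population(fac)
            if seasonal_weighting
            else float(fac.peak_population)
        )
        home = assign_cell(fac.lon, fac.lat, grid)
        d = great_circle_km(fac.lon, fac.lat, lon2, lat2)
        with np.errstate(divide="ignore"):
            contrib = pop / (np.pi * d**2)
            if remote_decay == "disc_ratio":
                contrib = contrib * areas / (np.pi * d**2)
        if home is not None:
            hc, hr = home
            contrib[hr, hc] = pop / areas[hr, hc]
        values += contrib
    return ValueLayer(grid, values * 1.0e4)  # km^-2 -> per 10,000 km^2
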