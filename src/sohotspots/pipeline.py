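"""End-to-end risk-map pipeline: inputs -> layers -> ranks -> maps A-F.

Each stage is a plain function over the library modules so the CLI
subcommands, tests and the full :func:`run_pipeline` share one code path.
"""

from __future__ import annotations

import logging
import shutil
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

from . import io as soio
from .aggregation import grid_point_samples, regrid_raster_geomean
from .grid import GridSpec
from .human_activity import (
    Facility,
    effective_population_density,
    ship_person_days,
)
from .layers import RankLayer, RiskMap, TrendLayer, ValueLayer
from .ranking import rank_layer, rank_trend_layer
from .risk_maps import build_all_maps, hotspot_cells
from .synthetic import SyntheticBundle, generate_all
from .trends import DailyField, MonthlyField, trend_map

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class InputBundle:
    grid: GridSpec
    krill_samples: pd.DataFrame
    chl_raster: xr.DataArray
    sst_field: DailyField | MonthlyField
    ph_field: MonthlyField
    ship_records: pd.DataFrame
    facilities: list[Facility]
    persons_aboard: dict[str, float]


def read_inputs(config: soio.PipelineConfig) -> InputBundle:
    """Load and validate all inputs named in the config, or synthesize them."""
    grid = config.grid()
    if config.synthesize:
        bundle: SyntheticBundle = generate_all(
            seed=config.seed, grid=grid, sst_freq=config.sst_freq
        )
        return InputBundle(
            grid=grid,
            krill_samples=bundle.krill_samples,
            chl_raster=bundle.chl_raster,
            sst_field=bundle.sst_field,
            ph_field=bundle.ph_field,
            ship_records=bundle.ship_records,
            facilities=bundle.facilities,
            persons_aboard=dict(config.persons_aboard),
        )
    paths = config.input_paths
    required = {"krill", "chlorophyll", "sst", "ph", "ships", "facilities"}
    missing = required - set(paths)
    if missing:
        raise soio.InputValidationError(f"input_paths missing entries: {sorted(missing)}")
    return InputBundle(
        grid=grid,
        krill_samples=soio.read_point_samples(paths["krill"]),
        chl_raster=soio.read_fine_raster(paths["chlorophyll"]),
        sst_field=soio.read_monthly_field(paths["sst"]),
        ph_field=soio.read_monthly_field(paths["ph"]),
        ship_records=soio.read_ship_records(paths["ships"]),
        facilities=soio.read_facilities(paths["facilities"]),
        persons_aboard=dict(config.persons_aboard),
    )


@dataclass
class PipelineResult:
    value_layers: dict[str, ValueLayer]
    trend_layers: dict[str, TrendLayer]
    rank_layers: dict[str, RankLayer]
    maps: dict[str, RiskMap]


def compute_layers(inputs: InputBundle, config: soio.PipelineConfig) -> PipelineResult:
    """Run every analysis stage in memory."""
    grid = inputs.grid
    months = frozenset(config.month_filter)
    oq = tuple(config.outlier_quantiles)
    reference = tuple(config.climatology_reference)

    stage = "grid-biota"
    try:
        krill = grid_point_samples(inputs.krill_samples, grid, months)
        chl = regrid_raster_geomean(inputs.chl_raster, grid)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, exc) from exc

    stage = "trends"
    try:
        sst_trend = trend_map(
            inputs.sst_field, reference, config.significance_alpha, config.trend_fit_on
        )
        ph_trend = trend_map(
            inputs.ph_field, reference, config.significance_alpha, config.trend_fit_on
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "human"
    try:
        _, ship_total = ship_person_days(
            inputs.ship_records, inputs.persons_aboard, grid
        )
        fac_density = effective_population_density(
            inputs.facilities,
            grid,
            seasonal_weighting=config.facility_seasonal_weighting,
            remote_decay=config.facility_remote_decay,
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "rank"
    try:
        ranks = {
            "krill": rank_layer(krill, "log", oq),
            "chlorophyll": rank_layer(chl, "log", oq),
            "sst": rank_trend_layer(sst_trend, "warming", oq),
            "ph": rank_trend_layer(ph_trend, "acidification", oq),
            "ships": rank_layer(ship_total, "log", oq),
            "facilities": rank_layer(fac_density, "log", oq),
        }
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "compose"
    try:
        maps = build_all_maps(
            ranks["krill"],
            ranks["chlorophyll"],
            ranks["sst"],
            ranks["ph"],
            ranks["ships"],
            ranks["facilities"],
            ship_mask_lat=config.ship_mask_lat,
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    return PipelineResult(
        value_layers={
            "krill": krill,
            "chlorophyll": chl,
            "ships": ship_total,
            "facilities": fac_density,
        },
        trend_layers={"sst": sst_trend, "ph": ph_trend},
        rank_layers=ranks,
        maps=maps,
    )


def run_pipeline(config: soio.PipelineConfig) -> Path:
    """Run everything and write the artefact directory; returns its path.

    Writes maps A-F as NetCDF and GeoJSON, all rank layers, and a YAML run
    report embedding the resolved config, fitted scales and input checksums.
    On failure the partially written directory is removed and a
    :class:`PipelineStageError` naming the stage is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        inputs = read_inputs(config)
        logger.info("inputs ready in %.1fs", time.time() - t0)
        result = compute_layers(inputs, config)
        logger.info("layers computed in %.1fs", time.time() - t0)

        for name, rmap in result.maps.items():
            soio.write_risk_map(rmap, out / f"map_{name}.nc")
            soio.write_geojson(
                soio.layer_to_geojson(
                    rmap.grid, rmap.scores, "score", map=name
                ),
                out / f"map_{name}.geojson",
            )
        for name, rlayer in result.rank_layers.items():
            soio.write_rank_layer(rlayer, out / f"rank_{name}.nc")

        report = {
            "config": _config_dict(config),
            "scales": {
                name: soio.rank_scale_to_dict(r.scale)
                for name, r in result.rank_layers.items()
                if r.scale is not None
            },
            "trend_errors": {
                name: t.errors for name, t in result.trend_layers.items()
            },
            "input_checksums": {
                name: soio.file_checksum(path)
                for name, path in config.input_paths.items()
                if Path(path).exists()
            },
            "top_hotspots": [
                {"col": c, "row": r, "score": float(result.maps["F"].scores[r, c])}
                for c, r in hotspot_cells(result.maps["F"], 1.0)[:10]
            ],
        }
        (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return out
    except PipelineStageError:
        shutil.rmtree(out, ignore_errors=True)
        raise
    except Exception as exc:  # noqa: BLE001
        shutil.rmtree(out, ignore_errors=True)
        raise PipelineStageError("io", exc) from exc


def _config_dict(config: soio.PipelineConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)
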