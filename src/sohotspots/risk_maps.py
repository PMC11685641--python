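"""Compose rank layers into baseline, interaction and combined risk maps.

Six maps mirror the standard layout of a multi-stressor overlap analysis:

* A — biota baseline: mean rank of krill and chlorophyll;
* C — abiotic baseline: mean rank of SST and pH trends;
* E — human activity: mean rank of ship traffic and facilities, restricted
  to cells south of 60°S (no ship data further north);
* B — emissions x biota interaction: mean of E and A;
* D — emissions x abiotic interaction: mean of E and C;
* F — combined "microplastic hotspot" map: mean of B and D.

Cell means use whichever contributing layers are present (a cell missing
krill is defined entirely by chlorophyll); the 60°S mask propagates from E
to B, D and F.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec
from .layers import RankLayer, RiskMap, require_same_grid

#: Northern limit of the human-activity layers (degrees latitude).
SHIP_DATA_NORTH_LIMIT = -60.0


def _scores_and_name(layer: RankLayer | RiskMap) -> tuple[np.ndarray, list[str]]:
    if isinstance(layer, RiskMap):
        return layer.scores, list(layer.provenance)
    return layer.ranks, []


def mean_rank(
    layers: list[RankLayer | RiskMap], names: list[str] | None = None
) -> RiskMap:
    """Per-cell arithmetic mean of the non-missing contributing layers.

    A cell missing in every layer stays missing; a cell missing in some
    layers takes the mean of those present.
    """
    if not layers:
        raise ValueError("mean_rank needs at least one layer")
    grid = require_same_grid(*layers)
    stack = []
    provenance: list[str] = []
    for i, layer in enumerate(layers):
        scores, inherited = _scores_and_name(layer)
        stack.append(scores)
        if names is not None:
            provenance.append(names[i])
        elif inherited:
            provenance.extend(inherited)
        else:
            provenance.append(f"layer{i}")
    provenance = list(dict.fromkeys(provenance))  # dedupe, keep order
    arr = np.stack(stack)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(arr), axis=0)
        scores = np.where(counts > 0, np.nansum(arr, axis=0) / np.maximum(counts, 1), np.nan)
    return RiskMap(grid, scores, provenance)


def mask_north_of(map_or_layer, lat_limit: float = SHIP_DATA_NORTH_LIMIT):
    """Return a copy with cells not entirely south of ``lat_limit`` missing."""
    grid: GridSpec = map_or_layer.grid
    lat_hi = grid.lat_south + (np.arange(grid.n_rows) + 1) * grid.lat_width
    keep = lat_hi <= lat_limit + 1e-9
    if isinstance(map_or_layer, RiskMap):
        scores = map_or_layer.scores.copy()
        scores[~keep, :] = np.nan
        return RiskMap(grid, scores, list(map_or_layer.provenance))
    ranks = map_or_layer.ranks.copy()
    ranks[~keep, :] = np.nan
    return RankLayer(grid, ranks, map_or_layer.scale)


def build_all_maps(
    krill: RankLayer,
    chlorophyll: RankLayer,
    sst: RankLayer,
    ph: RankLayer,
    ships: RankLayer,
    facilities: RankLayer,
    ship_mask_lat: float | None = SHIP_DATA_NORTH_LIMIT,
) -> dict[str, RiskMap]:
    """Compose the six maps A-F from the six input rank layers.

    ``ship_mask_lat`` restricts E (and everything downstream: B, D, F) to
    cells entirely south of that latitude; pass None to disable the mask.
    """
    require_same_grid(krill, chlorophyll, sst, ph, ships, facilities)
    a = mean_rank([krill, chlorophyll], names=["krill", "chlorophyll"])
    c = mean_rank([sst, ph], names=["sst_trend", "ph_trend"])
    e = mean_rank([ships, facilities], names=["ship_traffic", "facilities"])
    if ship_mask_lat is not None:
        e = mask_north_of(e, ship_mask_lat)
    b = mean_rank([e, a])
    d = mean_rank([e, c])
    f = mean_rank([b, d])
    if ship_mask_lat is not None:
        b = mask_north_of(b, ship_mask_lat)
        d = mask_north_of(d, ship_mask_lat)
        f = mask_north_of(f, ship_mask_lat)
    return {"A": a, "B": b, "C": c, "D": d, "E": e, "F": f}


def hotspot_cells(risk: RiskMap, threshold: float) -> list[tuple[int, int]]:
    """Cells with score >= threshold as (col, row), descending by score."""
    if not 1.0 <= threshold <= 5.0:
        raise ValueError("threshold must lie in [1, 5]")
    rows, cols = np.where(~np.isnan(risk.scores) & (risk.scores >= threshold))
    scores = risk.scores[rows, cols]
    order = np.argsort(-scores, kind="stable")
    return [(int(c), int(r)) for c, r in zip(cols[order], rows[order])]
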