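"""Per-cell data containers shared across the pipeline.

Every layer stores its values as a (n_rows, n_cols) float array aligned with
a :class:`~sohotspots.grid.GridSpec`; NaN marks missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec


class GridMismatchError(ValueError):
    """Layers combined across different grids."""


@dataclass
class ValueLayer:
    """Continuous per-cell values (density, concentration, person-days...).

    ``values`` is (n_rows, n_cols) with NaN for missing; ``n_obs`` counts the
    observations that contributed to each cell (0 where missing).
    """

    grid: GridSpec
    values: np.ndarray
    n_obs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.n_obs is None:
            self.n_obs = np.where(np.isnan(self.values), 0, 1).astype(int)
        else:
            self.n_obs = np.asarray(self.n_obs, dtype=int)
            if self.n_obs.shape != self.grid.shape:
                raise GridMismatchError("n_obs shape does not match grid")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a value is present."""
        return ~np.isnan(self.values)


@dataclass
class TrendLayer:
    """Per-cell linear-trend results (units yr^-1).

    All five arrays are (n_rows, n_cols); NaN marks cells where the trend
    chain could not run.  ``significant`` is a float array of 0/1/NaN so it
    shares the missingness convention.
    """

    grid: GridSpec
    gradient: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    errors: list[str] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.gradient)


@dataclass
class RankLayer:
    """Discrete 1-5 concern ranks per cell (NaN where the input was missing)."""

    grid: GridSpec
    ranks: np.ndarray
    scale: "object | None" = None  # RankScale; kept loose to avoid a cycle

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.shape != self.grid.shape:
            raise GridMismatchError("ranks shape does not match grid")
        present = self.ranks[~np.isnan(self.ranks)]
        if present.size and (present.min() < 1 or present.max() > 5):
            raise ValueError("ranks must lie in {1..5}")


@dataclass
class RiskMap:
    """Continuous mean-rank composite in [1, 5] per cell."""

    grid: GridSpec
    scores: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != self.grid.shape:
            raise GridMismatchError("scores shape does not match grid")
        if not self.provenance:
            raise ValueError("provenance must name the contributing layers")
        present = self.scores[~np.isnan(self.scores)]
        if present.size and (present.min() < 1 - 1e-9 or present.max() > 5 + 1e-9):
            raise ValueError("risk scores must lie in [1, 5]")


def require_same_grid(*layers) -> GridSpec:
    grids = {layer.grid for layer in layers}
    if len(grids) != 1:
        raise GridMismatchError("layers do not share a grid")
    return layers[0].grid
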