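"""Gridded covariate stacks and suitability surfaces.

One fixed raster convention is used throughout the package: projected
metre coordinates, cell-centre registration, row 0 at the north edge
(y decreases with row index).  ``origin`` is the (x, y) of the centre of
the north-west cell.  Masked cells (``mask == True``) are sea or
otherwise invalid and are excluded from every computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = ["CovariateStack", "SuitabilitySurface", "TEMPERATURE_PREFIX", "PRECIPITATION_PREFIX"]

TEMPERATURE_PREFIX = "temp_"
PRECIPITATION_PREFIX = "precip_"


@dataclass
class CovariateStack:
    """Named environmental layers sharing one grid, mask and georeferencing.

    Layers whose names start with ``temp_`` are treated as temperature-like
    (shifted additively by climate scenarios); names starting with
    ``precip_`` are precipitation-like (receive elevation-tapered scenario
    increments).  An ``elevation`` layer (metres above sea level) is
    required by most downstream operations.
    """

    cell_size: float
    origin: tuple[float, float]
    layers: dict[str, np.ndarray]
    mask: np.ndarray
    scenario_id: str = "current"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = self.mask.shape
        for name, grid in self.layers.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != shape:
                raise ValueError(f"layer {name!r} has shape {grid.shape}, mask has {shape}")
            self.layers[name] = grid
        if "elevation" in self.layers:
            elev = self.layers["elevation"]
            if np.any(elev[~self.mask] < 0):
                raise ValueError("elevation must be non-negative on land cells")
        for name, grid in self.layers.items():
            if not np.all(np.isfinite(grid[~self.mask])):
                raise ValueError(f"layer {name!r} has non-finite values on land cells")

    # -- basic geometry ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def elevation(self) -> np.ndarray:
        return self.layers["elevation"]

    @property
    def land(self) -> np.ndarray:
        """Boolean grid of valid (non-sea) cells."""
        return ~self.mask

    @property
    def n_land(self) -> int:
        return int(self.land.sum())

    def cell_center(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        return x0 + np.asarray(cols) * self.cell_size, y0 - np.asarray(rows) * self.cell_size

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices for point coordinates.

        Raises ``ValueError`` listing offending points outside the grid extent.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        x0, y0 = self.origin
        cols = np.rint((x - x0) / self.cell_size).astype(int)
        rows = np.rint((y0 - y) / self.cell_size).astype(int)
        bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
        if np.any(bad):
            offenders = [(float(xi), float(yi)) for xi, yi in zip(x[bad], y[bad])]
            raise ValueError(f"points outside grid extent: {offenders}")
        return rows, cols

    def value_at(self, layer: str, x, y) -> np.ndarray:
        """Nearest-cell lookup of one layer; masked cells yield NaN."""
        rows, cols = self.cell_index(x, y)
        vals = self.layers[layer][rows, cols].astype(float)
        vals[self.mask[rows, cols]] = np.nan
        return vals

    def covariates_at(self, names: Iterable[str], rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        return {name: self.layers[name][rows, cols] for name in names}

    def land_covariates(self, names: Iterable[str]) -> dict[str, np.ndarray]:
        land = self.land
        return {name: self.layers[name][land] for name in names}

    def temperature_layers(self) -> list[str]:
        return [n for n in self.layers if n.startswith(TEMPERATURE_PREFIX)]

    def precipitation_layers(self) -> list[str]:
        return [n for n in self.layers if n.startswith(PRECIPITATION_PREFIX)]

    def copy_with(self, layers: dict[str, np.ndarray], scenario_id: str) -> "CovariateStack":
        return CovariateStack(
            cell_size=self.cell_size,
            origin=self.origin,
            layers=layers,
            mask=self.mask.copy(),
            scenario_id=scenario_id,
        )


@dataclass
class SuitabilitySurface:
    """Per-cell habitat suitability for one species under one scenario."""

    values: np.ndarray
    mask: np.ndarray
    species: str = ""
    scenario_id: str = "current"
    output_kind: str = "logistic"
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        land = self.values[~self.mask]
        if land.size and (np.nanmin(land) < -1e-9 or np.nanmax(land) > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1] on land cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def land(self) -> np.ndarray:
        return ~self.mask

    def land_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def cell_index(self, x, y):
        helper = CovariateStack(
            cell_size=self.cell_size, origin=self.origin, layers={}, mask=self.mask,
        )
        return helper.cell_index(x, y)

    def value_at(self, x, y) -> np.ndarray:
        rows, cols = self.cell_index(x, y)
        vals = self.values[rows, cols].astype(float)
        vals[self.mask[rows, cols]] = np.nan
        return vals

    def with_values(self, values: np.ndarray, scenario_id: str | None = None) -> "SuitabilitySurface":
        return replace(self, values=values, scenario_id=scenario_id or self.scenario_id)
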