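"""Synthetic volcanic island with elevation-driven climate and survey data.

Emulates the study system behind the analysis: a single volcanic island
whose arid lowlands grade into humid highlands, two elevation transects
of vegetation plots, and tortoise dung piles carrying seed loads of two
invasive fruit species.  The generator provides a *known* true
suitability function so that the whole model-fitting and
wasted-dispersal pipeline can be validated by parameter recovery rather
than against unavailable field rasters.

All samplers are pure functions of their ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grids import CovariateStack, SuitabilitySurface

__all__ = [
    "TrueSuitabilityParams",
    "OccurrenceSet",
    "VegetationPlot",
    "DungPile",
    "SeedCountModel",
    "ThresholdLogisticOccupancy",
    "generate_island",
    "apply_scenario",
    "true_suitability",
    "sample_occurrences",
    "clean_occurrences",
    "sample_plots",
    "sample_dung_piles",
    "SITE_TRANSECTS",
]

# Coastal sea-level mean temperature (deg C) used by the generator; the
# lapse rate default of 6.5 degC/km is the standard environmental lapse.
COAST_TEMPERATURE = 25.0
DEFAULT_LAPSE_RATE = 6.5


@dataclass(frozen=True)
class TrueSuitabilityParams:
    """Parameters of the generating (true) suitability function.

    The surface is the product of two optional factors:

    * a Gaussian elevation response ``exp(-0.5 ((z - opt)/breadth)^2)``
      (disabled when ``opt_elevation`` is ``None``), and
    * a logistic response ``sigmoid(intercept + sum_k c_k x~_k)`` in
      land-standardised covariates (disabled when ``intercept`` is
      ``None`` and ``coefficients`` is empty),

    scaled by ``max_suitability``.  With only the elevation factor the
    value at the optimum is exactly ``max_suitability`` and the response
    is symmetric about it; with only the logistic factor and all
    coefficients zero the surface is the constant
    ``max_suitability * sigmoid(intercept)``.
    """

    opt_elevation: float | None = None
    breadth: float | None = None
    max_suitability: float = 1.0
    intercept: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.max_suitability <= 1.0):
            raise ValueError("max_suitability must lie in (0, 1]")
        if self.opt_elevation is not None:
            if self.breadth is None or self.breadth <= 0:
                raise ValueError("breadth must be positive when opt_elevation is set")


@dataclass
class OccurrenceSet:
    """Georeferenced presence records for one species."""

    species: str
    x: np.ndarray
    y: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass
class VegetationPlot:
    site: str
    x: float
    y: float
    elevation: float
    presence: dict[str, int]


@dataclass
class DungPile:
    site: str
    x: float
    y: float
    elevation: float
    seed_counts: dict[str, int]
    period: str = "survey"

    def __post_init__(self) -> None:
        for sp, n in self.seed_counts.items():
            if n < 0:
                raise ValueError(f"negative seed count for {sp!r}")


# ---------------------------------------------------------------------------
# Island and climate layers
# ---------------------------------------------------------------------------

def generate_island(
    seed: int = 0,
    n_rows: int = 120,
    n_cols: int = 120,
    peak_elevation: float = 860.0,
    cell_size: float = 100.0,
    lapse_rate: float = DEFAULT_LAPSE_RATE,
    coast_fraction: float = 0.92,
    relief_sd: float = 12.0,
    climate_noise_sd: float = 0.15,
) -> CovariateStack:
    """Build a radially symmetric volcanic island with climate layers.

    Elevation is a cone peaking at the island centre plus smoothed
    low-frequency relief, clipped to ``[0, peak_elevation]``; the sea is
    every cell beyond the coast radius.  Temperature layers decrease
    with elevation at ``lapse_rate`` degC per km; precipitation layers
    increase with elevation (the arid-lowland / humid-highland
    gradient).  Two smoothed pure-noise layers with no suitability
    signal are included as decoys for predictor selection.
    """
    if n_rows < 20 or n_cols < 20:
        raise ValueError("island grid must be at least 20 x 20 cells")
    if peak_elevation <= 0:
        raise ValueError("peak_elevation must be positive")
    rng = np.random.default_rng(seed)

    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    r = np.hypot((rows - cy), (cols - cx)) * cell_size
    r_coast = coast_fraction * min(n_rows, n_cols) / 2.0 * cell_size

    cone = peak_elevation * (1.0 - r / r_coast)
    relief = ndimage.gaussian_filter(rng.normal(size=(n_rows, n_cols)), sigma=4.0)
    relief *= relief_sd / max(relief.std(), 1e-12)
    elevation = np.clip(cone + relief, 0.0, peak_elevation)
    mask = cone <= 0.0
    elevation[mask] = 0.0

    def _noise(sd: float, sigma: float = 2.0) -> np.ndarray:
        smooth = ndimage.gaussian_filter(rng.normal(size=(n_rows, n_cols)), sigma=sigma)
        return smooth * sd / max(smooth.std(), 1e-12)

    km = elevation / 1000.0
    rel = elevation / peak_elevation
    # Moisture anomaly: a smooth windward/leeward field independent of
    # elevation, shared by the precipitation layers.  It breaks the
    # temperature-precipitation collinearity so a precipitation-limited
    # species is identifiable as such by predictor selection.
    moisture = _noise(1.0, sigma=6.0)
    layers = {
        "elevation": elevation,
        "temp_mean": COAST_TEMPERATURE - lapse_rate * km + _noise(climate_noise_sd),
        "temp_max": COAST_TEMPERATURE + 6.0 - lapse_rate * km + _noise(climate_noise_sd),
        "temp_min": COAST_TEMPERATURE - 6.0 - lapse_rate * km + _noise(climate_noise_sd),
        "precip_total": 400.0 + 1400.0 * rel + 300.0 * moisture + _noise(25.0),
        "precip_dry": 10.0 + 90.0 * rel + 30.0 * moisture + _noise(3.0),
        "precip_wet": 150.0 + 450.0 * rel + 120.0 * moisture + _noise(10.0),
        "noise_a": _noise(1.0),
        "noise_b": _noise(1.0),
    }
    for name in ("precip_total", "precip_dry", "precip_wet"):
        np.clip(layers[name], 0.0, None, out=layers[name])
    return CovariateStack(
        cell_size=cell_size,
        origin=(0.0, (n_rows - 1) * cell_size),
        layers=layers,
        mask=mask,
        scenario_id="current",
    )


def apply_scenario(
    stack: CovariateStack,
    delta_temp: float = 0.0,
    delta_precip_lowland: float = 0.0,
    scenario_id: str = "scenario",
) -> CovariateStack:
    """Perturb climate layers to represent a future-climate scenario.

    Temperature layers are shifted by ``delta_temp`` everywhere.
    Precipitation layers gain an elevation-tapered increment
    ``delta_precip_lowland * (1 - z / z_max_land)``: the full increment
    at the coast, none at the island summit ("lowland wetting").  The
    mask and elevation are unchanged.
    """
    z = stack.elevation
    z_max = float(z[stack.land].max())
    taper = np.clip(1.0 - z / z_max, 0.0, 1.0)
    layers: dict[str, np.ndarray] = {}
    for name, grid in stack.layers.items():
        if name.startswith("temp_"):
            layers[name] = grid + delta_temp
        elif name.startswith("precip_"):
            layers[name] = grid + delta_precip_lowland * taper
        else:
            layers[name] = grid.copy()
    return stack.copy_with(layers, scenario_id)


def true_suitability(stack: CovariateStack, params: TrueSuitabilityParams) -> SuitabilitySurface:
    """Evaluate the generating suitability function on the stack."""
    value = np.full(stack.shape, params.max_suitability, dtype=float)
    if params.opt_elevation is not None:
        z = stack.elevation
        value = value * np.exp(-0.5 * ((z - params.opt_elevation) / params.breadth) ** 2)
    if params.intercept is not None or params.coefficients:
        eta = np.full(stack.shape, params.intercept or 0.0, dtype=float)
        land = stack.land
        for name, coef in params.coefficients.items():
            grid = stack.layers[name]
            mu = grid[land].mean()
            sd = grid[land].std()
            eta = eta + coef * (grid - mu) / max(sd, 1e-12)
        value = value * expit(eta)
    value[stack.mask] = 0.0
    return SuitabilitySurface(
        values=value,
        mask=stack.mask,
        species="true",
        scenario_id=stack.scenario_id,
        output_kind="true",
        cell_size=stack.cell_size,
        origin=stack.origin,
    )


# ---------------------------------------------------------------------------
# Survey samplers
# ---------------------------------------------------------------------------

def sample_occurrences(
    surface: SuitabilitySurface,
    n_target: int,
    seed: int = 0,
    species: str = "species",
) -> OccurrenceSet:
    """Draw presence records with probability proportional to suitability.

    Land cells are proposed uniformly and accepted with probability
    ``s / max(s)`` until ``n_target`` records accumulate (cells may
    repeat).  Records take cell-centre coordinates.
    """
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    land_rows, land_cols = np.nonzero(surface.land)
    s = surface.values[land_rows, land_cols]
    s_max = s.max() if s.size else 0.0
    if s_max <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    p = s / s_max
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    while len(chosen) < n_target:
        m = max(2 * (n_target - len(chosen)), 64)
        idx = rng.integers(0, land_rows.size, size=m)
        accept = rng.random(m) < p[idx]
        chosen.extend(idx[accept][: n_target - len(chosen)].tolist())
    idx = np.asarray(chosen)
    helper = CovariateStack(cell_size=surface.cell_size, origin=surface.origin, layers={}, mask=surface.mask)
    x, y = helper.cell_center(land_rows[idx], land_cols[idx])
    return OccurrenceSet(species=species, x=x, y=y, source="synthetic")


def clean_occurrences(
    occ: OccurrenceSet,
    stack: CovariateStack,
    max_elevation: float = np.inf,
) -> OccurrenceSet:
    """Drop records on sea cells or above an elevation ceiling.

    Mirrors the usual coordinate-cleaning step for aggregated presence
    databases (points in the ocean, implausible elevations).  Surviving
    records keep their original order.
    """
    rows, cols = stack.cell_index(occ.x, occ.y)
    on_sea = stack.mask[rows, cols]
    elev = stack.elevation[rows, cols]
    keep = ~on_sea & (elev <= max_elevation)
    return OccurrenceSet(species=occ.species, x=occ.x[keep], y=occ.y[keep], source=occ.source)


@dataclass(frozen=True)
class ThresholdLogisticOccupancy:
    """Plot-occupancy rule: zero below a hard survival threshold, logistic above.

    P(present | s) = sigmoid(a + b s) for s >= threshold, else 0.  The
    hard floor encodes the generating "survival limit": living plants
    never occur where suitability falls below it.
    """

    threshold: float
    a: float = -2.0
    b: float = 6.0

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        p = expit(self.a + self.b * s)
        return np.where(s >= self.threshold, p, 0.0)


# Site transect bearings (unit row/col direction from island centre toward
# the coast).  LR descends the south slope, CF the east slope.
SITE_TRANSECTS: dict[str, tuple[float, float]] = {
    "LR": (1.0, 0.0),
    "CF": (0.0, 1.0),
}


def _transect_cells(stack: CovariateStack, site: str) -> tuple[np.ndarray, np.ndarray]:
    """Land cells of a corridor along the site's slope, coast to summit."""
    try:
        dr, dc = SITE_TRANSECTS[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_TRANSECTS)}")
    rows, cols = np.nonzero(stack.land)
    cy, cx = (stack.n_rows - 1) / 2.0, (stack.n_cols - 1) / 2.0
    along = (rows - cy) * dr + (cols - cx) * dc
    across = -(rows - cy) * dc + (cols - cx) * dr
    half_width = max(3.0, 0.08 * min(stack.n_rows, stack.n_cols))
    keep = (along >= 0) & (np.abs(across) <= half_width)
    return rows[keep], cols[keep]


def sample_plots(
    stack: CovariateStack,
    species_responses: dict[str, tuple[SuitabilitySurface, Callable[[np.ndarray], np.ndarray]]],
    site: str,
    elevation_range: tuple[float, float] = (10.0, 400.0),
    elevation_step: float = 50.0,
    plots_per_level: int = 4,
    seed: int = 0,
) -> list[VegetationPlot]:
    """Place vegetation plots on the site transect at fixed elevation levels.

    Levels are the range start followed by multiples of ``elevation_step``
    up to the range end (e.g. 10, 50, 100, ..., 400), with
    ``plots_per_level`` plots at the cells nearest each level.  Presence
    per species is Bernoulli with probability given by its occupancy
    rule evaluated at that species' true suitability at the plot cell
    (``species_responses`` maps species -> (true surface, rule)).
    """
    if elevation_step <= 0:
        raise ValueError("elevation_step must be positive")
    lo, hi = elevation_range
    rows, cols = _transect_cells(stack, site)
    elev = stack.elevation[rows, cols]
    if hi > elev.max() or lo < elev.min() - elevation_step:
        raise ValueError(
            f"requested elevation range {elevation_range} outside transect span "
            f"[{elev.min():.0f}, {elev.max():.0f}]"
        )
    levels = [lo] + [v for v in np.arange(elevation_step, hi + 0.5 * elevation_step, elevation_step) if v > lo]
    rng = np.random.default_rng(seed)
    plots: list[VegetationPlot] = []
    for level in levels:
        order = np.argsort(np.abs(elev - level), kind="stable")
        take = order[:plots_per_level]
        for j in take:
            r, c = int(rows[j]), int(cols[j])
            x, y = stack.cell_center(np.array([r]), np.array([c]))
            presence = {}
            for sp, (surface, rule) in species_responses.items():
                s = float(surface.values[r, c])
                p = float(np.asarray(rule(np.array([s])))[0])
                presence[sp] = int(rng.random() < p)
            plots.append(
                VegetationPlot(
                    site=site,
                    x=float(x[0]),
                    y=float(y[0]),
                    elevation=float(stack.elevation[r, c]),
                    presence=presence,
                )
            )
    return plots


@dataclass(frozen=True)
class SeedCountModel:
    """Zero-inflated shifted negative-binomial seed loads for one species.

    A pile carries the species with probability ``presence_prob``; a
    positive pile carries ``1 + NegBin`` seeds with positive-pile mean
    ``mean_seeds`` and NB dispersion ``dispersion`` (small values give
    the heavy overdispersion seen in real dung piles, where the SD of
    seed counts exceeds the mean).
    """

    presence_prob: float
    mean_seeds: float
    dispersion: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.presence_prob <= 1.0):
            raise ValueError("presence_prob must lie in [0, 1]")
        if self.mean_seeds < 1.0:
            raise ValueError("mean_seeds (positive-pile mean) must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        present = rng.random(n) < self.presence_prob
        counts = np.zeros(n, dtype=int)
        m = self.mean_seeds - 1.0
        if m > 0:
            k = self.dispersion
            p = k / (k + m)
            counts[present] = 1 + rng.negative_binomial(k, p, size=int(present.sum()))
        else:
            counts[present] = 1
        return counts


def sample_dung_piles(
    stack: CovariateStack,
    site: str,
    n_piles: int,
    count_models: dict[str, SeedCountModel],
    seed: int = 0,
    elevation_range: tuple[float, float] = (10.0, 420.0),
    band_width: float = 50.0,
    stratified: bool = True,
    period: str = "survey",
) -> list[DungPile]:
    """Collect dung piles along the site transect across the full elevation span.

    With ``stratified=True`` (the default, mirroring a collect-on-crossing
    design where a pile is taken each time a 50 m elevation level is
    crossed) piles are spread round-robin over 50 m elevation bands, so
    low-elevation, below-survival-limit cells are always represented.
    Seed counts per species come from the zero-inflated negative-binomial
    ``count_models`` and do not depend on location: tortoises carry seeds
    wherever they roam, which is exactly what makes dispersal "wasted"
    in unsuitable lowlands.
    """
    if n_piles < 1:
        raise ValueError("n_piles must be at least 1")
    rows, cols = _transect_cells(stack, site)
    elev = stack.elevation[rows, cols]
    lo, hi = elevation_range
    in_range = (elev >= lo) & (elev <= hi)
    rows, cols, elev = rows[in_range], cols[in_range], elev[in_range]
    if rows.size == 0:
        raise ValueError("no transect cells in requested elevation range")
    rng = np.random.default_rng(seed)

    if stratified:
        edges = np.arange(lo, hi + band_width, band_width)
        band = np.digitize(elev, edges)
        band_ids = [b for b in np.unique(band) if np.any(band == b)]
        picks: list[int] = []
        i = 0
        while len(picks) < n_piles:
            b = band_ids[i % len(band_ids)]
            members = np.nonzero(band == b)[0]
            picks.append(int(rng.choice(members)))
            i += 1
        idx = np.asarray(picks)
    else:
        idx = rng.integers(0, rows.size, size=n_piles)

    counts = {sp: model.draw(rng, n_piles) for sp, model in count_models.items()}
    piles: list[DungPile] = []
    for j in range(n_piles):
        r, c = int(rows[idx[j]]), int(cols[idx[j]])
        x, y = stack.cell_center(np.array([r]), np.array([c]))
        piles.append(
            DungPile(
                site=site,
                x=float(x[0]),
                y=float(y[0]),
                elevation=float(stack.elevation[r, c]),
                seed_counts={sp: int(counts[sp][j]) for sp in counts},
                period=period,
            )
        )
    return piles
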