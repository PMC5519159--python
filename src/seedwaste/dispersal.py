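"""Wasted seed dispersal: survival limits, dung-pile overlays, summaries.

The core statistic: a frugivore deposits seeds along its migration
route; any dung pile containing a species' seeds at a location whose
modelled habitat suitability falls strictly below that species'
*survival limit* (the minimum suitability at which living plants were
recorded in vegetation plots) is a wasted dispersal event.  Reports
follow the two conventions seen in field studies: percentages of
species-containing piles and of all piles, plus a seed-weighted
percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import SuitabilitySurface
from .island import DungPile, VegetationPlot

__all__ = [
    "SurvivalLimit",
    "WastedDispersalReport",
    "DistributionSummary",
    "SeedStats",
    "value_at",
    "estimate_survival_limit",
    "classify_wasted",
    "wasted_report",
    "scenario_sweep",
    "summarize_distribution",
    "seed_stats",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Presentation rounding: half-away-from-zero at ``ndigits`` decimals.

    Internal computations keep full precision; only printed tables round.
    """
    factor = 10.0**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def value_at(surface: SuitabilitySurface, x, y, allow_missing: bool = True) -> np.ndarray:
    """Nearest-cell lookup of surface values at point coordinates.

    Masked cells yield NaN when ``allow_missing``; otherwise they raise.
    Points outside the grid extent always raise, listing the offenders.
    """
    vals = surface.value_at(x, y)
    if not allow_missing and np.any(np.isnan(vals)):
        bad = np.nonzero(np.isnan(vals))[0].tolist()
        raise ValueError(f"points fall on masked cells at indices {bad}")
    return vals


@dataclass(frozen=True)
class SurvivalLimit:
    """Minimum suitability at which living plants of a species occur."""

    species: str
    limit: float
    provenance: str = "min-occupied-plot"

    def __post_init__(self) -> None:
        if not (0.0 <= self.limit <= 1.0):
            raise ValueError("survival limit must lie in [0, 1]")


def estimate_survival_limit(
    plots: Sequence[VegetationPlot],
    surface: SuitabilitySurface,
    species: str,
) -> SurvivalLimit:
    """Survival limit = minimum modelled suitability over occupied plots."""
    occupied = [p for p in plots if p.presence.get(species, 0)]
    if not occupied:
        raise ValueError(f"no plot contains {species!r}; survival limit undefined")
    suit = value_at(
        surface,
        np.array([p.x for p in occupied]),
        np.array([p.y for p in occupied]),
        allow_missing=False,
    )
    return SurvivalLimit(species=species, limit=float(suit.min()))


def classify_wasted(
    piles: Sequence[DungPile],
    surface: SuitabilitySurface,
    limit: SurvivalLimit | float,
    species: str,
) -> np.ndarray:
    """Flag piles whose seeds land strictly below the survival limit.

    A pile is wasted iff it contains at least one seed of the species
    AND the suitability at its location is < limit (strict: a pile at
    exactly the limit sits at a presence-compatible value and is not
    wasted).  A pile on a masked cell is an error.
    """
    lim = limit.limit if isinstance(limit, SurvivalLimit) else float(limit)
    suit = value_at(
        surface,
        np.array([p.x for p in piles]),
        np.array([p.y for p in piles]),
        allow_missing=False,
    )
    has_seeds = np.array([p.seed_counts.get(species, 0) > 0 for p in piles])
    return has_seeds & (suit < lim)


@dataclass
class WastedDispersalReport:
    """Wasted-dispersal tallies for one species under one scenario."""

    species: str
    scenario_id: str
    n_piles_below: int
    n_species_piles: int
    n_all_piles: int
    seeds_wasted: int
    seeds_total: int

    @property
    def pct_of_species_piles(self) -> float:
        return 100.0 * self.n_piles_below / self.n_species_piles if self.n_species_piles else 0.0

    @property
    def pct_of_all_piles(self) -> float:
        return 100.0 * self.n_piles_below / self.n_all_piles if self.n_all_piles else 0.0

    @property
    def pct_seeds_wasted(self) -> float:
        return 100.0 * self.seeds_wasted / self.seeds_total if self.seeds_total else 0.0

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "scenario_id": self.scenario_id,
            "n_piles_below": self.n_piles_below,
            "n_species_piles": self.n_species_piles,
            "n_all_piles": self.n_all_piles,
            "seeds_wasted": self.seeds_wasted,
            "seeds_total": self.seeds_total,
            "pct_of_species_piles": self.pct_of_species_piles,
            "pct_of_all_piles": self.pct_of_all_piles,
            "pct_seeds_wasted": self.pct_seeds_wasted,
        }


def wasted_report(
    piles: Sequence[DungPile],
    flags: np.ndarray,
    species: str,
    scenario_id: str = "current",
) -> WastedDispersalReport:
    """Aggregate per-pile wasted flags into counts and percentages."""
    flags = np.asarray(flags, dtype=bool)
    if flags.shape[0] != len(piles):
        raise ValueError("flags must align with piles")
    counts = np.array([p.seed_counts.get(species, 0) for p in piles])
    return WastedDispersalReport(
        species=species,
        scenario_id=scenario_id,
        n_piles_below=int(flags.sum()),
        n_species_piles=int((counts > 0).sum()),
        n_all_piles=len(piles),
        seeds_wasted=int(counts[flags].sum()),
        seeds_total=int(counts.sum()),
    )


def scenario_sweep(
    piles: Sequence[DungPile],
    surfaces: dict[str, SuitabilitySurface],
    limit: SurvivalLimit | float,
    species: str,
) -> list[WastedDispersalReport]:
    """One wasted-dispersal report per scenario, same limit throughout.

    The survival limit is a property of the species' response, not of
    any particular map, so the current-climate limit is reused against
    each scenario's suitability values at the fixed pile locations.
    """
    reports = []
    for scenario_id, surface in surfaces.items():
        flags = classify_wasted(piles, surface, limit, species)
        reports.append(wasted_report(piles, flags, species, scenario_id))
    return reports


@dataclass
class DistributionSummary:
    """Elevation and suitability ranges of a species' records at one site."""

    species: str
    site: str
    kind: str  # "plot" | "pile"
    n_units: int
    n_present: int
    elevation_min: float
    elevation_mean: float
    elevation_max: float
    suitability_min: float
    suitability_mean: float
    suitability_max: float

    @property
    def presence_pct(self) -> float:
        return 100.0 * self.n_present / self.n_units if self.n_units else 0.0

    @property
    def empty(self) -> bool:
        return self.n_present == 0

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "site": self.site,
            "kind": self.kind,
            "n_units": self.n_units,
            "n_present": self.n_present,
            "presence_pct": self.presence_pct,
            "elevation_min": self.elevation_min,
            "elevation_mean": self.elevation_mean,
            "elevation_max": self.elevation_max,
            "suitability_min": self.suitability_min,
            "suitability_mean": self.suitability_mean,
            "suitability_max": self.suitability_max,
        }


def _contains(unit, species: str) -> bool:
    if isinstance(unit, DungPile):
        return unit.seed_counts.get(species, 0) > 0
    return bool(unit.presence.get(species, 0))


def summarize_distribution(
    units: Sequence[VegetationPlot] | Sequence[DungPile],
    surface: SuitabilitySurface,
    species: str,
    kind: str,
) -> DistributionSummary:
    """Presence share and elevation/suitability ranges over survey units.

    Ranges are computed over units containing the species; a species
    absent from every unit yields presence 0 with NaN ranges, explicitly
    marked via ``summary.empty``.
    """
    if not units:
        raise ValueError("units must be non-empty")
    site = units[0].site
    present = [u for u in units if _contains(u, species)]
    if not present:
        return DistributionSummary(
            species=species, site=site, kind=kind, n_units=len(units), n_present=0,
            elevation_min=float("nan"), elevation_mean=float("nan"), elevation_max=float("nan"),
            suitability_min=float("nan"), suitability_mean=float("nan"), suitability_max=float("nan"),
        )
    elev = np.array([u.elevation for u in present], dtype=float)
    suit = value_at(
        surface,
        np.array([u.x for u in present]),
        np.array([u.y for u in present]),
        allow_missing=False,
    )
    return DistributionSummary(
        species=species, site=site, kind=kind, n_units=len(units), n_present=len(present),
        elevation_min=float(elev.min()), elevation_mean=float(elev.mean()), elevation_max=float(elev.max()),
        suitability_min=float(suit.min()), suitability_mean=float(suit.mean()), suitability_max=float(suit.max()),
    )


@dataclass
class SeedStats:
    """Seed-load statistics for one species over a pile collection.

    Both per-positive-pile and per-all-piles means are reported because
    field summaries use both denominators.  SD is the sample standard
    deviation over positive piles.
    """

    species: str
    total_seeds: int
    n_piles: int
    n_positive_piles: int
    mean_per_positive_pile: float
    sd_per_positive_pile: float
    max_count: int
    mean_per_pile: float

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "total_seeds": self.total_seeds,
            "n_piles": self.n_piles,
            "n_positive_piles": self.n_positive_piles,
            "mean_per_positive_pile": self.mean_per_positive_pile,
            "sd_per_positive_pile": self.sd_per_positive_pile,
            "max_count": self.max_count,
            "mean_per_pile": self.mean_per_pile,
        }


def seed_stats(piles: Sequence[DungPile], species: str) -> SeedStats:
    """Totals, positive-pile mean/SD/max and all-pile mean seed counts."""
    if not piles:
        raise ValueError("piles must be non-empty")
    counts = np.array([p.seed_counts.get(species, 0) for p in piles], dtype=float)
    pos = counts[counts > 0]
    return SeedStats(
        species=species,
        total_seeds=int(counts.sum()),
        n_piles=len(piles),
        n_positive_piles=int(pos.size),
        mean_per_positive_pile=float(pos.mean()) if pos.size else 0.0,
        sd_per_positive_pile=float(pos.std(ddof=1)) if pos.size > 1 else 0.0,
        max_count=int(counts.max()),
        mean_per_pile=float(counts.mean()),
    )
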