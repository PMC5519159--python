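"""Seed-flux and suitability-front projection arithmetic.

Two back-of-envelope projections that turn wasted-dispersal fractions
into ecologically interpretable rates:

* the change in the number of seeds deposited into *suitable* habitat
  per day/year when the wasted fraction shifts between scenarios, for a
  disperser population of known size and defecation rate; and
* the advance rate of the suitability front (metres per year) and the
  per-generation dispersal distance a plant needs to keep pace with it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FluxParams", "FrontParams", "seed_flux_change", "front_advance", "DAYS_PER_YEAR"]

DAYS_PER_YEAR = 365  # calendar convention; no leap handling


@dataclass(frozen=True)
class FluxParams:
    """Inputs of the seed-flux projection.

    ``mean_seeds_per_pile`` is the all-pile mean (zeros included), since
    every defecation event counts toward the flux.
    """

    population: float          # number of dispersing animals
    defecation_rate: float     # dung piles per animal per day
    mean_seeds_per_pile: float
    wasted_fraction_current: float
    wasted_fraction_future: float

    def __post_init__(self) -> None:
        if min(self.population, self.defecation_rate, self.mean_seeds_per_pile) < 0:
            raise ValueError("population, rate and seed mean must be non-negative")
        for frac in (self.wasted_fraction_current, self.wasted_fraction_future):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("wasted fractions must lie in [0, 1]")


def seed_flux_change(p: FluxParams) -> tuple[float, float]:
    """Extra seeds landing in suitable habitat per day and per year.

    per_day = N * rate * mean_seeds * (wasted_current - wasted_future);
    positive when wasted dispersal declines (more seeds land well).
    """
    per_day = (
        p.population
        * p.defecation_rate
        * p.mean_seeds_per_pile
        * (p.wasted_fraction_current - p.wasted_fraction_future)
    )
    return per_day, per_day * DAYS_PER_YEAR


@dataclass(frozen=True)
class FrontParams:
    """Inputs of the suitability-front projection.

    ``horizon_years`` defaults to 55, reading a mid-2010s baseline
    against a 2070 scenario horizon.
    """

    advance_distance_m: float
    horizon_years: float = 55.0
    generation_time_years: float = 8.0

    def __post_init__(self) -> None:
        if min(self.advance_distance_m, self.horizon_years, self.generation_time_years) <= 0:
            raise ValueError("all front parameters must be positive")


def front_advance(p: FrontParams) -> tuple[float, float]:
    """Front speed (m/yr) and required dispersal distance per generation.

    Full precision is returned; presentation layers round to integers.
    """
    m_per_year = p.advance_distance_m / p.horizon_years
    return m_per_year, m_per_year * p.generation_time_years
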