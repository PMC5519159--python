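"""Scenario projection and range gain/loss accounting.

Projects a fitted suitability model onto future-climate covariate stacks
and tallies the cells switching between suitable and unsuitable when
both maps are binarized at a common threshold — the standard range-size
bookkeeping used to summarise climate-driven range shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import CovariateStack, SuitabilitySurface
from .maxent import MaxentModel, predict

__all__ = ["RangeChangeReport", "project", "range_change"]


def project(
    model: MaxentModel,
    scenario_stack: CovariateStack,
    output_kind: str = "logistic",
    species: str = "",
) -> SuitabilitySurface:
    """Apply a fitted model to a (possibly future-climate) stack.

    Covariates beyond the training range are clamped by the feature
    scalers; the scenario id of the stack propagates to the surface.
    """
    return predict(model, scenario_stack, output_kind=output_kind, species=species)


@dataclass
class RangeChangeReport:
    """Cell transitions between binarized current and future ranges.

    ``suitable`` means suitability >= threshold (closed at the
    threshold, the complement of the strict-< rule used for wasted
    dispersal).  Percentages are reported on both denominators found in
    practice: all land cells, and currently suitable cells.
    """

    threshold: float
    n_lost: int
    n_gained: int
    n_stable_suitable: int
    n_stable_unsuitable: int

    @property
    def n_land(self) -> int:
        return self.n_lost + self.n_gained + self.n_stable_suitable + self.n_stable_unsuitable

    @property
    def n_current_suitable(self) -> int:
        return self.n_lost + self.n_stable_suitable

    @property
    def n_future_suitable(self) -> int:
        return self.n_gained + self.n_stable_suitable

    @property
    def pct_gain_of_land(self) -> float:
        return 100.0 * self.n_gained / self.n_land

    @property
    def pct_loss_of_land(self) -> float:
        return 100.0 * self.n_lost / self.n_land

    @property
    def pct_gain_of_current(self) -> float:
        cur = self.n_current_suitable
        return 100.0 * self.n_gained / cur if cur else float("nan")

    @property
    def pct_loss_of_current(self) -> float:
        cur = self.n_current_suitable
        return 100.0 * self.n_lost / cur if cur else float("nan")

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_lost": self.n_lost,
            "n_gained": self.n_gained,
            "n_stable_suitable": self.n_stable_suitable,
            "n_stable_unsuitable": self.n_stable_unsuitable,
            "n_land": self.n_land,
            "pct_gain_of_land": self.pct_gain_of_land,
            "pct_loss_of_land": self.pct_loss_of_land,
            "pct_gain_of_current": self.pct_gain_of_current,
            "pct_loss_of_current": self.pct_loss_of_current,
        }


def range_change(
    current: SuitabilitySurface,
    future: SuitabilitySurface,
    threshold: float,
) -> RangeChangeReport:
    """Count suitable/unsuitable transitions between two surfaces.

    Both surfaces are binarized at ``suitability >= threshold``; the
    four transition classes partition the land cells exactly.
    """
    if current.shape != future.shape or np.any(current.mask != future.mask):
        raise ValueError("current and future surfaces must share shape and mask")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    land = current.land
    cur = current.values[land] >= threshold
    fut = future.values[land] >= threshold
    return RangeChangeReport(
        threshold=threshold,
        n_lost=int(np.sum(cur & ~fut)),
        n_gained=int(np.sum(~cur & fut)),
        n_stable_suitable=int(np.sum(cur & fut)),
        n_stable_unsuitable=int(np.sum(~cur & ~fut)),
    )
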