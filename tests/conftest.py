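import numpy as np
import pytest

from seedwaste import (
    CovariateStack,
    SuitabilitySurface,
    TrueSuitabilityParams,
    generate_island,
    true_suitability,
)


@pytest.fixture(scope="session")
def island():
    """A mid-sized synthetic island shared across read-only tests."""
    return generate_island(seed=7, n_rows=60, n_cols=60, peak_elevation=860.0)


@pytest.fixture(scope="session")
def wet_species_surface(island):
    """True suitability of a precipitation-limited (lowland-excluded) species."""
    params = TrueSuitabilityParams(
        intercept=-1.0, coefficients={"precip_dry": 2.2, "precip_wet": 1.2}
    )
    return true_suitability(island, params)


def flat_surface(value: float, n: int = 8, cell: float = 1.0) -> SuitabilitySurface:
    """Constant suitability surface on an all-land square grid."""
    return SuitabilitySurface(
        values=np.full((n, n), value),
        mask=np.zeros((n, n), dtype=bool),
        cell_size=cell,
        origin=(0.0, (n - 1) * cell),
    )


def surface_from_values(values, cell: float = 1.0) -> SuitabilitySurface:
    values = np.asarray(values, dtype=float)
    return SuitabilitySurface(
        values=values,
        mask=np.zeros(values.shape, dtype=bool),
        cell_size=cell,
        origin=(0.0, (values.shape[0] - 1) * cell),
    )
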