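"""Shared fixtures: small simulation runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from afplight import (
    annular_layout,
    homogeneous_grid,
    simulate,
    table_properties,
)


@pytest.fixture(scope="session")
def native650_volume():
    """Desk-scale 72-fiber run in native liver at 650 nm (shared, ~5 s)."""
    grid = homogeneous_grid(table_properties("native", 650))
    layout = annular_layout(n_fibers=72)
    return simulate(grid, layout, photons_per_fiber=3000, seed=11)


@pytest.fixture(scope="session")
def tiny_grid():
    """A coarse 20^3-voxel homogeneous grid for oracle comparisons."""
    from afplight.optics import OpticalProperties

    props = OpticalProperties(mu_a=0.5, mu_s_prime=10.0, g=0.9, n=1.33)
    return homogeneous_grid(props, extent=(4.0, 4.0, 2.0), voxel_size=0.2)
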