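"""Perturbative PA forward model and field-of-view summaries."""

import math

import numpy as np
import pytest

from afplight.grid import FluenceVolume, homogeneous_grid
from afplight.optics import OpticalProperties
from afplight.pa import (
    AbsorberSpec,
    PAFieldMap,
    absorber_mask,
    field_width,
    pa_amplitude_at,
    penetration_depth,
)


def make_volume(nfr: np.ndarray, voxel: float = 0.5) -> FluenceVolume:
    props = OpticalProperties(mu_a=0.1, mu_s_prime=10.0, g=0.7)
    extent = tuple(s * voxel for s in nfr.shape)
    grid = homogeneous_grid(props, extent=extent, voxel_size=voxel)
    return FluenceVolume(
        grid=grid,
        nfr=nfr.astype(float),
        launched_weight=1.0,
        deposited_weight=1.0,
        escaped_weight=0.0,
        seed=0,
        photons_per_fiber=1,
        n_fibers=1,
    )


def exp_map(decay: float = 1.0) -> PAFieldMap:
    """Toy map with on-axis amplitude exp(-decay * z), flat laterally."""
    depths = np.linspace(0.0, 8.0, 161)
    laterals = np.array([-1.0, 0.0, 1.0])
    amp = np.tile(np.exp(-decay * depths), (3, 1))
    amp_db = 20.0 * np.log10(amp / amp.max())
    return PAFieldMap(lateral_positions=laterals, depths=depths, amplitude_db=amp_db)


class TestPaAmplitude:
    def test_zero_fluence_region_gives_zero(self):
        nfr = np.zeros((10, 10, 10))
        nfr[:, :, :2] = 1.0  # all fluence near the surface
        vol = make_volume(nfr)
        deep = AbsorberSpec(geometry="line", position=(0.0, 0.0, 4.0),
                            mu_a_absorber=50.0)
        assert pa_amplitude_at(vol, deep) == 0.0

    def test_linearity_in_absorber_mu_a_and_gamma(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.random((10, 10, 10)))
        spec1 = AbsorberSpec(geometry="inclusion", size=1.5,
                             position=(0.0, 0.0, 2.0), mu_a_absorber=1.0)
        spec2 = AbsorberSpec(geometry="inclusion", size=1.5,
                             position=(0.0, 0.0, 2.0), mu_a_absorber=2.0)
        a1 = pa_amplitude_at(vol, spec1)
        assert pa_amplitude_at(vol, spec2) == pytest.approx(2 * a1)
        assert pa_amplitude_at(vol, spec1, gamma=3.0) == pytest.approx(3 * a1)

    def test_symmetric_positions_give_equal_amplitude(self):
        # Build a laterally symmetric fluence field by construction.
        nx = 11
        x = np.arange(nx) - nx // 2
        X, Y, Z = np.meshgrid(x, x, np.arange(8), indexing="ij")
        nfr = np.exp(-0.1 * (X**2 + Y**2) - 0.3 * Z)
        vol = make_volume(nfr)
        left = AbsorberSpec(geometry="line", position=(0.0, -1.5, 2.0))
        right = AbsorberSpec(geometry="line", position=(0.0, 1.5, 2.0))
        assert pa_amplitude_at(vol, left) == pytest.approx(
            pa_amplitude_at(vol, right), rel=1e-9
        )

    def test_absorber_outside_grid_raises(self):
        vol = make_volume(np.ones((6, 6, 6)))
        with pytest.raises(ValueError):
            pa_amplitude_at(
                vol, AbsorberSpec(geometry="line", position=(0.0, 0.0, 50.0))
            )


class TestAbsorberMask:
    def test_tube_cross_section_area(self):
        props = OpticalProperties(mu_a=0.1, mu_s_prime=10.0, g=0.7)
        grid = homogeneous_grid(props, extent=(10.0, 10.0, 10.0), voxel_size=0.1)
        tube = AbsorberSpec(geometry="tube", size=1.0, position=(0.0, 0.0, 5.0),
                            orientation="x")
        mask = absorber_mask(grid, tube)
        # Cross-section voxel count approximates pi * r^2 within a voxel layer.
        per_slice = mask.sum() / grid.shape[0]
        area_expected = math.pi * 0.5**2 / 0.1**2
        ring = math.pi * 1.0 / 0.1  # one voxel layer around the perimeter
        assert abs(per_slice - area_expected) <= ring

    def test_subvoxel_line_snaps_to_nearest_column(self):
        props = OpticalProperties(mu_a=0.1, mu_s_prime=10.0, g=0.7)
        grid = homogeneous_grid(props, extent=(4.0, 4.0, 4.0), voxel_size=0.5)
        thin = AbsorberSpec(geometry="line", size=0.19, position=(0.0, 0.2, 2.1))
        mask = absorber_mask(grid, thin)
        assert mask.any()

    def test_validation(self):
        with pytest.raises(ValueError):
            AbsorberSpec(geometry="blob")
        with pytest.raises(ValueError):
            AbsorberSpec(geometry="line", size=-1.0)


class TestFieldSummaries:
    def test_exponential_map_minus20db_depth(self):
        """A(z) = exp(-z) crosses -20 dB at z = ln(10)."""
        pa_map = exp_map(decay=1.0)
        depth, crossed = penetration_depth(pa_map, -20.0)
        assert crossed
        assert depth == pytest.approx(math.log(10.0), abs=0.05)

    def test_threshold_zero_rejected_and_uncrossed_flagged(self):
        pa_map = exp_map(decay=0.01)  # never reaches -20 dB over 8 mm
        with pytest.raises(ValueError):
            penetration_depth(pa_map, 0.0)
        depth, crossed = penetration_depth(pa_map, -20.0)
        assert not crossed
        assert depth == pytest.approx(pa_map.depths[-1])

    def test_rectangular_profile_width_recovery(self):
        laterals = np.linspace(-5.0, 5.0, 101)
        depths = np.array([1.0])
        amp = np.where(np.abs(laterals) <= 2.0, 1.0, 1e-4)[:, None]
        amp_db = 20.0 * np.log10(amp / amp.max())
        pa_map = PAFieldMap(lateral_positions=laterals, depths=depths,
                            amplitude_db=amp_db)
        width, crossed = field_width(pa_map, -35.0, 1.0)
        assert crossed
        # Edges interpolate within one lateral sample of the true 4 mm.
        assert width == pytest.approx(4.0, abs=0.2)

    def test_symmetric_profile_symmetric_width(self):
        laterals = np.linspace(-5.0, 5.0, 201)
        depths = np.array([2.0])
        amp = np.exp(-0.5 * laterals**2)[:, None]
        amp_db = 20.0 * np.log10(amp / amp.max())
        pa_map = PAFieldMap(lateral_positions=laterals, depths=depths,
                            amplitude_db=amp_db)
        width, _ = field_width(pa_map, -35.0, 2.0)
        # -35 dB: 20 log10 A = -35 -> |x| = sqrt(2 ln(10^(35/20)))
        half = math.sqrt(2 * math.log(10 ** (35 / 20)))
        assert width == pytest.approx(2 * half, abs=0.1)

    def test_map_normalization_invariant(self):
        pa_map = exp_map()
        assert float(pa_map.amplitude_db.max()) == pytest.approx(0.0, abs=1e-12)
        assert np.all(pa_map.amplitude_db <= 1e-12)
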