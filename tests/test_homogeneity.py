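"""NFR_rel depth profiles and the optimal-depth statistic."""

import numpy as np
import pytest

from afplight.grid import FluenceVolume, homogeneous_grid
from afplight.homogeneity import (
    DepthProfile,
    nfr_rel_profile,
    optimal_depth,
    sweep_table,
)
from afplight.optics import OpticalProperties


def make_volume(nfr: np.ndarray, voxel: float = 0.5) -> FluenceVolume:
    props = OpticalProperties(mu_a=1.0, mu_s_prime=10.0, g=0.9)
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


def brute_force_nfr_rel(nfr: np.ndarray, roi_vox: int) -> np.ndarray:
    """Elementwise reference: loop over slices, explicit ROI mean / max."""
    nx, ny, nz = nfr.shape
    x0 = (nx - roi_vox) // 2
    y0 = (ny - roi_vox) // 2
    out = []
    for iz in range(nz):
        sl = nfr[:, :, iz]
        if sl.max() == 0:
            continue
        total = 0.0
        for i in range(x0, x0 + roi_vox):
            for j in range(y0, y0 + roi_vox):
                total += sl[i, j]
        out.append(100.0 * (total / roi_vox**2) / sl.max())
    return np.array(out)


class TestNfrRelProfile:
    def test_uniform_slice_is_100_percent(self):
        vol = make_volume(np.ones((8, 8, 4)))
        profile = nfr_rel_profile(vol, roi_side=2.0)
        assert np.allclose(profile.nfr_rel, 100.0)

    def test_hot_voxel_outside_roi_gives_zero(self):
        nfr = np.zeros((9, 9, 1))
        nfr[0, 0, 0] = 5.0  # corner, outside any centered ROI
        vol = make_volume(nfr)
        profile = nfr_rel_profile(vol, roi_side=1.0)
        assert profile.nfr_rel[0] == 0.0

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(0)
        nfr = rng.random((5, 5, 3))
        vol = make_volume(nfr)
        profile = nfr_rel_profile(vol, roi_side=1.5)  # 3x3 voxels
        expected = brute_force_nfr_rel(nfr, 3)
        assert np.allclose(profile.nfr_rel, expected, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        nfr = rng.random((6, 6, 5))
        p1 = nfr_rel_profile(make_volume(nfr), roi_side=1.0)
        p2 = nfr_rel_profile(make_volume(nfr * 137.5), roi_side=1.0)
        assert np.allclose(p1.nfr_rel, p2.nfr_rel, atol=1e-9)

    def test_zero_slices_dropped_with_warning(self):
        nfr = np.ones((4, 4, 3))
        nfr[:, :, 1] = 0.0
        with pytest.warns(UserWarning):
            profile = nfr_rel_profile(make_volume(nfr), roi_side=1.0)
        assert profile.depths.size == 2

    def test_all_zero_volume_raises(self):
        with pytest.raises(ValueError):
            nfr_rel_profile(make_volume(np.zeros((4, 4, 2))), roi_side=1.0)

    def test_roi_wider_than_grid_raises(self):
        with pytest.raises(ValueError):
            nfr_rel_profile(make_volume(np.ones((4, 4, 2))), roi_side=10.0)

    def test_non_integer_roi_snaps_and_records_side(self):
        vol = make_volume(np.ones((8, 8, 2)), voxel=0.5)
        profile = nfr_rel_profile(vol, roi_side=1.7)  # snaps to 3 voxels
        assert profile.roi_side == pytest.approx(1.5)


class TestOptimalDepth:
    def test_decreasing_profile_peaks_at_first_bin(self):
        profile = DepthProfile(
            depths=np.arange(0.25, 3.0, 0.25),
            nfr_rel=np.linspace(90, 10, 11),
            roi_side=1.0,
        )
        assert optimal_depth(profile, z_min=0.0) == pytest.approx(0.25)

    def test_tie_breaks_to_shallower_depth(self):
        profile = DepthProfile(
            depths=np.array([0.5, 1.0, 1.5]),
            nfr_rel=np.array([50.0, 80.0, 80.0]),
            roi_side=1.0,
        )
        assert optimal_depth(profile, z_min=0.0, bin_width=0.5) == pytest.approx(1.0)

    def test_z_min_excludes_launch_artifacts(self):
        profile = DepthProfile(
            depths=np.array([0.05, 1.0, 2.0]),
            nfr_rel=np.array([100.0, 60.0, 70.0]),
            roi_side=1.0,
        )
        assert optimal_depth(profile, z_min=0.1, bin_width=None) == pytest.approx(2.0)

    def test_empty_profile_raises(self):
        profile = DepthProfile(
            depths=np.array([0.05]), nfr_rel=np.array([10.0]), roi_side=1.0
        )
        with pytest.raises(ValueError):
            optimal_depth(profile, z_min=1.0)

    def test_binning_centers_on_width_multiples(self):
        profile = DepthProfile(
            depths=np.array([0.9, 1.0, 1.1, 1.4, 1.5, 1.6]),
            nfr_rel=np.array([10, 20, 30, 40, 50, 60.0]),
            roi_side=1.0,
        )
        binned = profile.binned(0.5)
        assert np.allclose(binned.depths, [1.0, 1.5])
        assert np.allclose(binned.nfr_rel, [20.0, 50.0])


def test_native650_simulation_optimum_near_2mm(native650_volume):
    """72-fiber native-liver 650 nm run peaks near the 2 mm literature depth."""
    profile = nfr_rel_profile(native650_volume)
    depth = optimal_depth(profile)
    assert 1.5 <= depth <= 2.5


def test_profile_invariants_on_simulation(native650_volume):
    profile = nfr_rel_profile(native650_volume)
    assert np.all(profile.nfr_rel >= 0)
    assert np.all(profile.nfr_rel <= 100)
    assert np.all(np.diff(profile.depths) > 0)


def test_sweep_table_is_tidy():
    profiles = [
        DepthProfile(
            depths=np.array([0.5, 1.0]),
            nfr_rel=np.array([10.0, 20.0]),
            roi_side=1.0,
            config_label="4 fibers",
        ),
        DepthProfile(
            depths=np.array([0.5, 1.0]),
            nfr_rel=np.array([30.0, 40.0]),
            roi_side=1.0,
            config_label="72 fibers",
        ),
    ]
    table = sweep_table(profiles, seed=5)
    assert list(table.columns) == ["depth_mm", "nfr_rel_pct", "config_label", "seed"]
    assert len(table) == 4
    assert set(table["config_label"]) == {"4 fibers", "72 fibers"}
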