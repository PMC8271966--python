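"""Voxelized tissue volumes and fluence-rate accumulators.

Coordinate convention (mm everywhere): the probe axis is +z, z = 0 at the
fiber-face (launch) plane increasing into tissue; x and y are centered on
the probe axis, so a grid of extent (ex, ey, ez) spans
x, y in [-ex/2, ex/2] x [-ey/2, ey/2] and z in [0, ez].  Voxel values are
taken at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import OpticalProperties

__all__ = ["VoxelGrid", "FluenceVolume", "homogeneous_grid"]

#: Default desk-scale domain, mm: matches the simulated liver cube.
DEFAULT_EXTENT_MM = (4.0, 4.0, 5.0)
#: Default desk-scale voxel pitch, mm (80 x 80 x 100 voxels).
DEFAULT_VOXEL_MM = 0.05


@dataclass
class VoxelGrid:
    """A rectangular voxel volume with per-region optical properties.

    ``region_map`` holds a small-integer region label per voxel (shape
    (nx, ny, nz)); ``region_properties`` maps each label to its
    :class:`~afplight.optics.OpticalProperties`.
    """

    extent: tuple[float, float, float]
    voxel_size: float
    region_map: np.ndarray
    region_properties: dict[int, OpticalProperties]

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        expect = tuple(
            int(round(e / self.voxel_size)) for e in self.extent
        )
        for e, n_vox in zip(self.extent, expect):
            if abs(e / self.voxel_size - n_vox) > 1e-6:
                raise ValueError(
                    f"extent {self.extent} mm is not an integer number of "
                    f"{self.voxel_size} mm voxels"
                )
        if (nx, ny, nz) != expect:
            raise ValueError(
                f"region_map shape {self.region_map.shape} does not match "
                f"extent/voxel_size {expect}"
            )
        labels = np.unique(self.region_map)
        missing = [int(r) for r in labels if int(r) not in self.region_properties]
        if missing:
            raise ValueError(f"region labels without properties: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.region_map.shape)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=x, 1=y, 2=z), mm."""
        n = self.shape[axis]
        if axis == 2:
            return (np.arange(n) + 0.5) * self.voxel_size
        return (np.arange(n) + 0.5) * self.voxel_size - self.extent[axis] / 2.0

    def origin_offsets(self) -> tuple[float, float, float]:
        """Offsets turning physical mm coordinates into voxel-index space."""
        return (self.extent[0] / 2.0, self.extent[1] / 2.0, 0.0)

    def property_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-label (mu_a, mu_s, g, mu_s_prime) arrays in cm^-1, label-indexed."""
        n = max(self.region_properties) + 1
        mu_a = np.zeros(n)
        mu_s = np.zeros(n)
        g = np.zeros(n)
        mu_sp = np.zeros(n)
        for label, props in self.region_properties.items():
            mu_a[label] = props.mu_a
            mu_s[label] = props.mu_s
            g[label] = props.g
            mu_sp[label] = props.mu_s_prime
        return mu_a, mu_s, g, mu_sp

    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size / 10.0) ** 3


def homogeneous_grid(
    props: OpticalProperties,
    extent: tuple[float, float, float] = DEFAULT_EXTENT_MM,
    voxel_size: float = DEFAULT_VOXEL_MM,
) -> VoxelGrid:
    """A single-region grid filled with one set of optical properties."""
    shape = tuple(int(round(e / voxel_size)) for e in extent)
    return VoxelGrid(
        extent=tuple(float(e) for e in extent),
        voxel_size=float(voxel_size),
        region_map=np.zeros(shape, dtype=np.int32),
        region_properties={0: props},
    )


@dataclass
class FluenceVolume:
    """Normalized fluence rate (NFR) on a voxel grid with weight bookkeeping.

    ``nfr`` is fluence rate per unit incident power, 1/cm^2 (W per W0 per
    cm^2), shape equal to ``grid.shape``.  ``launched_weight`` equals
    ``deposited_weight + escaped_weight`` to within 1e-6 relative on every
    run; the escaped total includes the (zero-mean) net Russian-roulette
    residual so the identity holds exactly per run.
    """

    grid: VoxelGrid
    nfr: np.ndarray
    launched_weight: float
    deposited_weight: float
    escaped_weight: float
    seed: int
    photons_per_fiber: int
    n_fibers: int
    ballistic_escape: bool = False

    @property
    def n_photons(self) -> int:
        return self.photons_per_fiber * self.n_fibers

    def conservation_residual(self) -> float:
        """|launched - deposited - escaped| / launched."""
        return abs(
            self.launched_weight - self.deposited_weight - self.escaped_weight
        ) / self.launched_weight

    def slice_at_depth(self, z_mm: float) -> np.ndarray:
        """Transverse (x, y) NFR slice nearest the requested depth."""
        iz = int(np.clip(round(z_mm / self.grid.voxel_size - 0.5), 0,
                         self.grid.shape[2] - 1))
        return self.nfr[:, :, iz]

    def on_axis_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(depths mm, NFR) along the central voxel column."""
        nx, ny, _ = self.grid.shape
        return self.grid.axis_coords(2), self.nfr[nx // 2, ny // 2, :]

    def symmetrized_d4(self) -> "FluenceVolume":
        """Average the volume over the dihedral symmetries of the x-y plane.

        Exact variance reduction for configurations whose source
        distribution shares the square grid's symmetry group (rotations by
        90 degrees plus axis/diagonal reflections) — e.g. an axis-centered
        annular layout with a fiber count divisible by 4 in a laterally
        homogeneous, square-extent medium.  The expected fluence is
        invariant under these operations, so averaging the 8 images leaves
        the estimate unbiased while cutting its variance.  Do not use for
        asymmetric layouts or media.
        """
        if self.grid.extent[0] != self.grid.extent[1]:
            raise ValueError("D4 symmetrization requires a square lateral extent")
        acc = np.zeros_like(self.nfr)
        for arr in (self.nfr, np.transpose(self.nfr, (1, 0, 2))):
            for k in range(4):
                acc += np.rot90(arr, k, axes=(0, 1))
        out = FluenceVolume(
            grid=self.grid,
            nfr=acc / 8.0,
            launched_weight=self.launched_weight,
            deposited_weight=self.deposited_weight,
            escaped_weight=self.escaped_weight,
            seed=self.seed,
            photons_per_fiber=self.photons_per_fiber,
            n_fibers=self.n_fibers,
            ballistic_escape=self.ballistic_escape,
        )
        return out
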