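"""Synthetic phantoms and scenes for transport and metric validation.

Generates every input the pipeline consumes, mirroring the experimental
scenes: the intralipid/India-ink liquid phantom with a thin line absorber,
layered chicken-over-liver volumes with embedded blood-tube / tumor-mimic /
ablation-lesion inclusions, slab targets at configurable depth for the
surface-vs-interstitial comparison, and PA-image-like 2D arrays whose
region contrasts are known by construction so the SNR metric can be tested
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .optics import ABLATED_70C, OpticalProperties, table_properties
from .pa import AbsorberSpec

__all__ = [
    "SceneSpec",
    "LayerSpec",
    "liquid_phantom",
    "layered_scene",
    "synthetic_pa_image",
    "chicken_properties",
    "blood_properties",
    "scene_library",
]

#: Chicken-mimicking medium: mu_a 0.1 cm^-1, mu_s' 10 cm^-1 around 680 nm.
CHICKEN_MU_A = 0.1
CHICKEN_MU_S_PRIME = 10.0
#: Whole-blood absorption default, within the 2-7 cm^-1 range at 760 nm.
BLOOD_MU_A = 4.0
#: Intralipid-like anisotropy used for the liquid phantom.
INTRALIPID_G = 0.7


def chicken_properties(wavelength: float = 680.0) -> OpticalProperties:
    """Chicken-breast-mimicking optical properties (liquid-phantom match)."""
    return OpticalProperties(
        mu_a=CHICKEN_MU_A, mu_s_prime=CHICKEN_MU_S_PRIME, g=0.9, n=1.33,
        wavelength=wavelength,
    )


def blood_properties(mu_a: float = BLOOD_MU_A, wavelength: float = 760.0
                     ) -> OpticalProperties:
    """Whole-blood-like properties for tube inclusions."""
    return OpticalProperties(mu_a=mu_a, mu_s_prime=15.0, g=0.95, n=1.33,
                             wavelength=wavelength)


def liquid_phantom(
    mu_a: float,
    mu_s_prime: float,
    extent=(24.0, 24.0, 16.0),
    voxel_size: float = 0.2,
    g: float = INTRALIPID_G,
    n: float = 1.33,
) -> VoxelGrid:
    """Homogeneous intralipid/ink liquid phantom with tunable mu_a, mu_s'.

    Defaults to a field-of-view-scale domain (24 x 24 x 16 mm at 0.2 mm
    voxels) rather than the 4 x 4 x 5 mm transport default, since the
    measured PA field spans about +/-10 mm laterally.
    """
    if mu_a < 0 or mu_s_prime < 0:
        raise ValueError("optical coefficients must be >= 0")
    props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s_prime, g=g, n=n)
    shape = tuple(int(round(e / voxel_size)) for e in extent)
    return VoxelGrid(
        extent=tuple(float(e) for e in extent),
        voxel_size=float(voxel_size),
        region_map=np.zeros(shape, dtype=np.int32),
        region_properties={0: props},
    )


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: label name, thickness (mm), optical properties."""

    name: str
    thickness: float
    properties: OpticalProperties

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass
class SceneSpec:
    """A layered scene with optional embedded inclusions.

    ``inclusions`` pair an :class:`~afplight.pa.AbsorberSpec` geometry with
    the optical properties to assign to its voxels; ``image_noise`` is
    (background mean, multiplicative speckle sigma) for derived synthetic
    images.
    """

    name: str
    layers: tuple[LayerSpec, ...]
    inclusions: tuple[tuple[AbsorberSpec, OpticalProperties], ...] = ()
    image_noise: tuple[float, float] = (0.05, 0.2)
    lateral_extent: tuple[float, float] = (20.0, 20.0)
    voxel_size: float = 0.25


def layered_scene(spec: SceneSpec) -> tuple[VoxelGrid, list[AbsorberSpec]]:
    """Materialize a layered scene as a voxel grid plus its inclusion specs.

    Layers stack along +z from the surface (z = 0); each inclusion's voxels
    are relabeled with its own properties.  Inclusions that fall entirely
    outside the volume raise ``ValueError``.
    """
    from .pa import absorber_mask

    depth = sum(layer.thickness for layer in spec.layers)
    ex, ey = spec.lateral_extent
    vox = spec.voxel_size
    # Round the total depth up to a whole voxel count.
    nz = int(round(depth / vox))
    if abs(nz * vox - depth) > 1e-6:
        raise ValueError("layer thicknesses must tile the voxel size")
    shape = (int(round(ex / vox)), int(round(ey / vox)), nz)
    region_map = np.zeros(shape, dtype=np.int32)
    props: dict[int, OpticalProperties] = {}
    z_edges = np.cumsum([0.0] + [layer.thickness for layer in spec.layers])
    zs = (np.arange(nz) + 0.5) * vox
    for idx, layer in enumerate(spec.layers):
        sel = (zs >= z_edges[idx]) & (zs < z_edges[idx + 1])
        region_map[:, :, sel] = idx
        props[idx] = layer.properties
    grid = VoxelGrid(
        extent=(float(ex), float(ey), float(nz * vox)),
        voxel_size=vox,
        region_map=region_map,
        region_properties=props,
    )
    absorbers = []
    label = len(spec.layers)
    for absorber, inc_props in spec.inclusions:
        mask = absorber_mask(grid, absorber)
        if not mask.any():
            raise ValueError(f"inclusion {absorber.label!r} outside the volume")
        region_map[mask] = label
        props[label] = inc_props
        absorbers.append(absorber)
        label += 1
    # Re-validate with the new labels in place.
    grid = VoxelGrid(
        extent=grid.extent,
        voxel_size=vox,
        region_map=region_map,
        region_properties=props,
    )
    return grid, absorbers


def scene_library(slab_depth: float = 15.0) -> dict[str, SceneSpec]:
    """Named scene presets mirroring the validation experiments.

    ``slab_target_15mm`` / ``slab_target_32mm``: an absorbing slab below a
    chicken layer at the two tested depths; ``blood_tube``: a 1 mm-ID tube
    of blood in chicken; ``tumor_inclusion``: a blood-soaked inclusion at
    the chicken/liver interface; ``ablation_lesion``: an ablated-liver
    region inside native liver under a chicken layer.
    """
    chicken = chicken_properties()
    liver_650 = table_properties("native", 650)
    ablated_650 = table_properties(ABLATED_70C, 650)
    ink_slab = OpticalProperties(mu_a=20.0, mu_s_prime=10.0, g=0.9, n=1.33)

    lib = {}
    for depth in (15.0, 32.0):
        lib[f"slab_target_{int(depth)}mm"] = SceneSpec(
            name=f"slab_target_{int(depth)}mm",
            layers=(LayerSpec("chicken", 40.0, chicken),),
            inclusions=(
                (
                    AbsorberSpec(
                        geometry="slab", size=2.0, position=(0.0, 0.0, depth),
                        mu_a_absorber=ink_slab.mu_a, label="ink_target",
                    ),
                    ink_slab,
                ),
            ),
        )
    lib["blood_tube"] = SceneSpec(
        name="blood_tube",
        layers=(LayerSpec("chicken", 30.0, chicken),),
        inclusions=(
            (
                AbsorberSpec(
                    geometry="tube", size=1.0, position=(0.0, 0.0, 20.0),
                    orientation="x", mu_a_absorber=BLOOD_MU_A, label="blood_tube",
                ),
                blood_properties(),
            ),
        ),
    )
    lib["tumor_inclusion"] = SceneSpec(
        name="tumor_inclusion",
        layers=(
            LayerSpec("chicken", 20.0, chicken),
            LayerSpec("liver", 20.0, liver_650),
        ),
        inclusions=(
            (
                AbsorberSpec(
                    geometry="inclusion", size=10.0, position=(0.0, 0.0, 20.0),
                    mu_a_absorber=BLOOD_MU_A, label="tumor_mimic",
                ),
                blood_properties(),
            ),
        ),
    )
    lib["ablation_lesion"] = SceneSpec(
        name="ablation_lesion",
        layers=(
            LayerSpec("chicken", 10.0, chicken),
            LayerSpec("liver", 30.0, liver_650),
        ),
        inclusions=(
            (
                AbsorberSpec(
                    geometry="inclusion", size=15.0, position=(0.0, 0.0, 25.0),
                    mu_a_absorber=ablated_650.mu_a, label="ablation_lesion",
                ),
                ablated_650,
            ),
        ),
    )
    return lib


def synthetic_pa_image(
    contrasts_db: dict[str, float],
    shape: tuple[int, int] = (128, 128),
    background_mean: float = 0.05,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """A PA-image-like 2D array with structures at known dB contrasts.

    Draws one rectangular structure per entry of ``contrasts_db`` (probe
    tip, tines, tube walls, ...) at mean level
    ``background_mean * 10**(dB/20)`` over a noisy background, applying
    multiplicative log-normal speckle of sigma ``noise_sigma`` everywhere.
    Returns ``(image, structure masks, background mask)``; the masks make
    the ground-truth SNR of every structure exact by construction.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    image = np.full(shape, background_mean, dtype=float)
    masks: dict[str, np.ndarray] = {}
    n = len(contrasts_db)
    # Structures tile the image in a row, each in its own cell with margins.
    cell_w = w // max(n, 1)
    for k, (name, c_db) in enumerate(sorted(contrasts_db.items())):
        level = background_mean * 10.0 ** (c_db / 20.0)
        mask = np.zeros(shape, dtype=bool)
        r0, r1 = h // 3, 2 * h // 3
        c0 = k * cell_w + cell_w // 4
        c1 = k * cell_w + 3 * cell_w // 4
        mask[r0:r1, c0:c1] = True
        image[mask] = level
        masks[name] = mask
    if noise_sigma > 0:
        # Mean-one log-normal speckle keeps region means (hence SNR) unbiased.
        speckle = rng.lognormal(
            mean=-0.5 * noise_sigma**2, sigma=noise_sigma, size=shape
        )
        image = image * speckle
    background = np.ones(shape, dtype=bool)
    for mask in masks.values():
        background &= ~mask
    # Keep a guard band between structures and sampled background.
    return image, masks, background
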