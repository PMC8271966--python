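"""Straightforward per-photon reference transport, for validation.

A deliberately plain re-statement of the voxel Monte Carlo rules using the
standard-library RNG and no array tricks, vectorization or early
termination shortcuts.  It is orders of magnitude slower than
:func:`afplight.transport.simulate` and exists so the optimized kernel can
be checked against an independent implementation on tiny grids.
"""

from __future__ import annotations

import math
import random

import numpy as np

from .grid import FluenceVolume, VoxelGrid
from .probe import ProbeLayout

__all__ = ["reference_simulate"]


def _sample_trunc_gauss(rng: random.Random, sigma: float, bound: float) -> float:
    while True:
        v = abs(rng.gauss(0.0, sigma))
        if v <= bound:
            return v


def reference_simulate(
    grid: VoxelGrid,
    layout: ProbeLayout,
    photons_per_fiber: int,
    seed: int = 0,
) -> FluenceVolume:
    """Reference transport run; same contract as ``transport.simulate``.

    Uses its own launch sampling and RNG, so agreement with the optimized
    kernel is statistical, not bitwise.
    """
    rng = random.Random(seed)
    mu_a_cm, mu_s_cm, g_arr, _ = grid.property_arrays()
    mu_a = mu_a_cm / 10.0  # mm^-1
    mu_s = mu_s_cm / 10.0
    nx, ny, nz = grid.shape
    half_x, half_y, _ = grid.origin_offsets()
    vox = grid.voxel_size
    score = np.zeros(grid.shape)
    deposited = 0.0
    escaped = 0.0
    n_medium = next(iter(grid.region_properties.values())).n

    for fiber in layout.fibers:
        fx, fy, fz = fiber.position
        ax = np.asarray(fiber.axis, dtype=float)
        # Local frame for the fiber face.
        ref = np.array([1.0, 0.0, 0.0])
        if abs(float(ref @ ax)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ ax) * ax
        u /= np.linalg.norm(u)
        v = np.cross(ax, u)
        core_r = fiber.core_diameter / 2.0
        theta_max = math.asin(fiber.numerical_aperture / n_medium)

        for _ in range(photons_per_fiber):
            # Launch: truncated Gaussian spot + truncated Gaussian cone.
            while True:
                dx = rng.gauss(0.0, core_r / 2.0)
                dy = rng.gauss(0.0, core_r / 2.0)
                if math.hypot(dx, dy) <= core_r:
                    break
            p = np.array([fx, fy, fz]) + dx * u + dy * v
            if theta_max > 0.0:
                theta = _sample_trunc_gauss(rng, theta_max / 2.0, theta_max)
            else:
                theta = 0.0
            phi = rng.uniform(0.0, 2.0 * math.pi)
            d = (
                math.cos(theta) * ax
                + math.sin(theta) * math.cos(phi) * u
                + math.sin(theta) * math.sin(phi) * v
            )
            x, y, z = float(p[0]), float(p[1]), float(p[2])
            ux, uy, uz = float(d[0]), float(d[1]), float(d[2])
            w = 1.0
            while True:
                ix = math.floor((x + half_x) / vox)
                iy = math.floor((y + half_y) / vox)
                iz = math.floor(z / vox)
                if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
                    escaped += w
                    break
                r = int(grid.region_map[ix, iy, iz])
                mut = mu_a[r] + mu_s[r]
                if mut <= 0.0:
                    x += ux * vox
                    y += uy * vox
                    z += uz * vox
                    continue
                step = -math.log(rng.random()) / mut
                x += ux * step
                y += uy * step
                z += uz * step
                ix = math.floor((x + half_x) / vox)
                iy = math.floor((y + half_y) / vox)
                iz = math.floor(z / vox)
                if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
                    escaped += w
                    break
                r = int(grid.region_map[ix, iy, iz])
                mut = mu_a[r] + mu_s[r]
                if mut <= 0.0:
                    continue
                score[ix, iy, iz] += w / mut
                absorb = w * mu_a[r] / mut
                deposited += absorb
                w -= absorb
                if w <= 0.0:
                    break
                gg = float(g_arr[r])
                xi = rng.random()
                if gg != 0.0:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi)
                    cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    cost = min(1.0, max(-1.0, cost))
                else:
                    cost = 2.0 * xi - 1.0
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                sphi = rng.uniform(0.0, 2.0 * math.pi)
                cosp, sinp = math.cos(sphi), math.sin(sphi)
                if abs(uz) > 0.99999:
                    ux, uy = sint * cosp, sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    ux, uy, uz = (
                        sint * (ux * uz * cosp - uy * sinp) / den + ux * cost,
                        sint * (uy * uz * cosp + ux * sinp) / den + uy * cost,
                        -sint * cosp * den + uz * cost,
                    )
                if w < 1e-4:
                    if rng.random() < 0.1:
                        escaped -= 9.0 * w
                        w *= 10.0
                    else:
                        escaped += w
                        break

    n_total = photons_per_fiber * layout.n_fibers
    nfr = score * 0.1 / (grid.voxel_volume_cm3() * n_total)
    return FluenceVolume(
        grid=grid,
        nfr=nfr,
        launched_weight=float(n_total),
        deposited_weight=deposited,
        escaped_weight=escaped,
        seed=int(seed),
        photons_per_fiber=int(photons_per_fiber),
        n_fibers=layout.n_fibers,
    )
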