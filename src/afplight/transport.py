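"""Voxelized Monte Carlo photon transport.

Standard MCML-style transport on a voxel grid: exponential step sampling
with the total interaction coefficient mu_t = mu_a + mu_s of the voxel at
the photon's current position, partial weight deposition w * mu_a / mu_t at
each interaction, Henyey-Greenstein direction sampling with the local
anisotropy g, and Russian-roulette termination (threshold 1e-4, survival
chance 1/10 with 10x weight boost).  Photons crossing the grid boundary are
terminated and their weight booked as escaped; the medium index is uniform
so no Fresnel reflection or refraction occurs at internal boundaries.

Fluence is scored with the collision estimator: each interaction adds
w / mu_t to its voxel, which equals the deposited-energy estimator
(absorbed / mu_a) wherever mu_a > 0 and remains defined in non-absorbing
scattering regions.  The per-voxel normalized fluence rate is
score / (voxel volume * total photons), in 1/cm^2 per unit incident power.

Fibers are simulated sequentially with independent, fiber-indexed RNG
streams, so results are deterministic given (seed, layout, grid, photon
count) and independent of fiber ordering.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from numba import njit

from .grid import FluenceVolume, VoxelGrid
from .probe import ProbeLayout, sample_launch

__all__ = ["simulate", "rerun_equivalence", "WEIGHT_THRESHOLD", "ROULETTE_SURVIVAL"]

logger = logging.getLogger(__name__)

#: Roulette trigger weight and survival probability (MCML conventions).
WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@njit(cache=True)
def _transport_kernel(
    pos,          # (N, 3) launch positions, mm
    direc,        # (N, 3) unit launch directions
    region_map,   # (nx, ny, nz) int32 labels
    mu_a,         # per-label absorption, mm^-1
    mu_s,         # per-label scattering, mm^-1
    g,            # per-label anisotropy
    voxel,        # voxel pitch, mm
    half_x,       # extent_x / 2, mm
    half_y,       # extent_y / 2, mm
    score,        # (nx, ny, nz) accumulator for w / mu_t [mm]
    seed,         # uint32 RNG seed for this photon batch
):
    np.random.seed(seed)
    nx, ny, nz = region_map.shape
    deposited = 0.0
    escaped = 0.0
    n = pos.shape[0]
    for i in range(n):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        ux = direc[i, 0]
        uy = direc[i, 1]
        uz = direc[i, 2]
        w = 1.0
        while True:
            ix = int(math.floor((x + half_x) / voxel))
            iy = int(math.floor((y + half_y) / voxel))
            iz = int(math.floor(z / voxel))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                escaped += w
                break
            r = region_map[ix, iy, iz]
            mut = mu_a[r] + mu_s[r]
            if mut <= 0.0:
                # Free-space voxel: fly ballistically one voxel pitch.
                x += ux * voxel
                y += uy * voxel
                z += uz * voxel
                continue
            step = -math.log(np.random.random()) / mut
            x += ux * step
            y += uy * step
            z += uz * step
            ix = int(math.floor((x + half_x) / voxel))
            iy = int(math.floor((y + half_y) / voxel))
            iz = int(math.floor(z / voxel))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                escaped += w
                break
            r = region_map[ix, iy, iz]
            mut = mu_a[r] + mu_s[r]
            if mut <= 0.0:
                # Stepped into a free-space voxel: no interaction there.
                continue
            # Interaction: score collision, absorb, scatter.
            score[ix, iy, iz] += w / mut
            absorb = w * mu_a[r] / mut
            deposited += absorb
            w -= absorb
            if w <= 0.0:
                break
            gg = g[r]
            rnd = np.random.random()
            if gg != 0.0:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * rnd)
                cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
            else:
                cost = 2.0 * rnd - 1.0
            sint = math.sqrt(max(0.0, 1.0 - cost * cost))
            phi = 2.0 * math.pi * np.random.random()
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                denom = math.sqrt(1.0 - uz * uz)
                ux_n = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                uy_n = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                uz_n = -sint * cosp * denom + uz * cost
                ux, uy, uz = ux_n, uy_n, uz_n
            if w < 1e-4:
                # Roulette: survivors repay the killed weight so that
                # launched == deposited + escaped holds exactly per run.
                if np.random.random() < 0.1:
                    escaped -= 9.0 * w
                    w *= 10.0
                else:
                    escaped += w
                    break
    return deposited, escaped


def _fiber_seeds(seed: int, n_fibers: int) -> np.ndarray:
    """Deterministic, order-independent per-fiber RNG seeds (< 2^31)."""
    seeds = np.empty(n_fibers, dtype=np.uint32)
    for k in range(n_fibers):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(k,))
        seeds[k] = ss.generate_state(1, dtype=np.uint32)[0] % (2**31)
    return seeds


#: Desk-scale default photon budget per fiber.
DEFAULT_PHOTONS_PER_FIBER = 100_000


def simulate(
    grid: VoxelGrid,
    layout: ProbeLayout,
    photons_per_fiber: int = DEFAULT_PHOTONS_PER_FIBER,
    seed: int = 0,
) -> FluenceVolume:
    """Run the transport for every fiber in ``layout`` and sum the fluence.

    Each fiber launches ``photons_per_fiber`` photons sequentially from its
    own RNG stream; the normalized fluence rate accumulates additively over
    fibers and is normalized by the total launched photon count, matching a
    probe whose delivered power scales with the number of fibers.
    """
    if photons_per_fiber < 1:
        raise ValueError("photons_per_fiber must be >= 1")
    mu_a_cm, mu_s_cm, g_arr, _ = grid.property_arrays()
    mu_a_mm = np.ascontiguousarray(mu_a_cm / 10.0)
    mu_s_mm = np.ascontiguousarray(mu_s_cm / 10.0)
    g_arr = np.ascontiguousarray(g_arr)
    region_map = np.ascontiguousarray(grid.region_map.astype(np.int32))
    score = np.zeros(grid.shape, dtype=np.float64)
    half_x, half_y, _ = grid.origin_offsets()

    if np.all(mu_a_mm + mu_s_mm <= 0.0):
        logger.warning("all regions have mu_t = 0: photons escape ballistically")

    n_medium = next(iter(grid.region_properties.values())).n
    seeds = _fiber_seeds(seed, layout.n_fibers)
    deposited = 0.0
    escaped = 0.0
    for k, fiber in enumerate(layout.fibers):
        launch_rng = np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(k, 1))
            )
        )
        pos, direc, _ = sample_launch(
            fiber, launch_rng, n_medium=n_medium, size=photons_per_fiber
        )
        dep, esc = _transport_kernel(
            np.ascontiguousarray(pos),
            np.ascontiguousarray(direc),
            region_map,
            mu_a_mm,
            mu_s_mm,
            g_arr,
            grid.voxel_size,
            half_x,
            half_y,
            score,
            seeds[k],
        )
        deposited += dep
        escaped += esc

    n_total = photons_per_fiber * layout.n_fibers
    # score holds sum of w / mu_t with mu_t in mm^-1 -> pathlength in mm;
    # convert to cm and divide by voxel volume (cm^3) and photon count.
    nfr = score * 0.1 / (grid.voxel_volume_cm3() * n_total)
    vol = FluenceVolume(
        grid=grid,
        nfr=nfr,
        launched_weight=float(n_total),
        deposited_weight=deposited,
        escaped_weight=escaped,
        seed=int(seed),
        photons_per_fiber=int(photons_per_fiber),
        n_fibers=layout.n_fibers,
        ballistic_escape=bool(np.all(mu_a_mm + mu_s_mm <= 0.0)),
    )
    residual = vol.conservation_residual()
    logger.info(
        "transport: %d photons, conservation residual %.3g", n_total, residual
    )
    if residual > 1e-6:
        raise RuntimeError(
            f"energy conservation violated: residual {residual:.3g} > 1e-6"
        )
    return vol


def rerun_equivalence(
    grid: VoxelGrid,
    layout: ProbeLayout,
    photons_per_fiber: int,
    seed: int,
) -> bool:
    """True iff two runs with identical arguments are bit-identical."""
    a = simulate(grid, layout, photons_per_fiber, seed)
    b = simulate(grid, layout, photons_per_fiber, seed)
    return bool(np.array_equal(a.nfr, b.nfr))
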