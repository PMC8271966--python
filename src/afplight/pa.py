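"""Photoacoustic forward model and field-of-view analysis.

The initial photoacoustic pressure generated by an absorber is
proportional to the product of its absorption coefficient and the local
light fluence.  This module evaluates that proportionality for small
embedded absorbers against a simulated fluence volume, builds relative PA
amplitude maps over a grid of absorber positions (in dB re the map
maximum, 20*log10 convention for a pressure-like quantity), and extracts
field-of-view summaries: on-axis penetration depth and lateral field width
at a dB threshold.

The absorber is treated perturbatively: the fluence is computed once for
the absorber-free medium and the absorber probes it without re-running
transport.  This first-order approximation is appropriate for thin targets
(the reference target is a 0.19 mm line) in a centimeter-scale field, and
all maps are relative, not absolute pressures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import FluenceVolume, VoxelGrid

__all__ = [
    "AbsorberSpec",
    "PAFieldMap",
    "absorber_mask",
    "pa_amplitude_at",
    "field_map",
    "penetration_depth",
    "field_width",
]

#: Diameter of the reference line target (black hair), mm.
LINE_ABSORBER_DIAMETER_MM = 0.19


@dataclass(frozen=True)
class AbsorberSpec:
    """A small absorbing target embedded in the medium.

    ``geometry`` is one of ``line`` (thin cylinder along ``orientation``),
    ``tube`` (same voxelization as line, semantic label for blood-filled
    tubes), ``slab`` (infinite transverse slab of given thickness) or
    ``inclusion`` (sphere of given diameter).  ``size`` is the diameter
    (line/tube/inclusion) or thickness (slab), mm.
    """

    geometry: str
    size: float = LINE_ABSORBER_DIAMETER_MM
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "x"
    mu_a_absorber: float = 100.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.geometry not in ("line", "tube", "slab", "inclusion"):
            raise ValueError(f"unknown absorber geometry {self.geometry!r}")
        if self.size <= 0:
            raise ValueError("absorber size must be positive")
        if self.orientation not in ("x", "y", "z"):
            raise ValueError("orientation must be 'x', 'y' or 'z'")
        if self.mu_a_absorber < 0:
            raise ValueError("mu_a_absorber must be >= 0")


def absorber_mask(grid: VoxelGrid, absorber: AbsorberSpec) -> np.ndarray:
    """Boolean voxel mask of the absorber; raises if fully outside the grid."""
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    px, py, pz = absorber.position
    half = absorber.size / 2.0
    if absorber.geometry == "slab":
        mask = np.abs(Z - pz) <= half
    elif absorber.geometry == "inclusion":
        mask = (X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2 <= half**2
    else:  # line or tube: cylinder along the orientation axis
        if absorber.orientation == "x":
            mask = (Y - py) ** 2 + (Z - pz) ** 2 <= half**2
        elif absorber.orientation == "y":
            mask = (X - px) ** 2 + (Z - pz) ** 2 <= half**2
        else:
            mask = (X - px) ** 2 + (Y - py) ** 2 <= half**2
    if not mask.any():
        # Thin targets can fall between voxel centers: snap to the nearest
        # voxel column/plane so sub-voxel absorbers remain representable.
        if absorber.geometry == "slab":
            iz = int(np.argmin(np.abs(zs - pz)))
            if abs(zs[iz] - pz) > half + grid.voxel_size:
                raise ValueError("absorber lies outside the grid")
            mask[:, :, iz] = True
        elif absorber.geometry == "inclusion":
            ix = int(np.argmin(np.abs(xs - px)))
            iy = int(np.argmin(np.abs(ys - py)))
            iz = int(np.argmin(np.abs(zs - pz)))
            mask[ix, iy, iz] = True
        else:
            if absorber.orientation == "x":
                iy = int(np.argmin(np.abs(ys - py)))
                iz = int(np.argmin(np.abs(zs - pz)))
                if (
                    abs(ys[iy] - py) > half + grid.voxel_size
                    or abs(zs[iz] - pz) > half + grid.voxel_size
                ):
                    raise ValueError("absorber lies outside the grid")
                mask[:, iy, iz] = True
            elif absorber.orientation == "y":
                ix = int(np.argmin(np.abs(xs - px)))
                iz = int(np.argmin(np.abs(zs - pz)))
                mask[ix, :, iz] = True
            else:
                ix = int(np.argmin(np.abs(xs - px)))
                iy = int(np.argmin(np.abs(ys - py)))
                mask[ix, iy, :] = True
    # Reject positions outside the physical domain.
    if not (
        -grid.extent[0] / 2 - half <= px <= grid.extent[0] / 2 + half
        and -grid.extent[1] / 2 - half <= py <= grid.extent[1] / 2 + half
        and -half <= pz <= grid.extent[2] + half
    ):
        raise ValueError("absorber position lies outside the grid")
    return mask


def pa_amplitude_at(
    fluence: FluenceVolume,
    absorber: AbsorberSpec,
    gamma: float = 1.0,
) -> float:
    """Relative PA amplitude gamma * mu_a_absorber * mean NFR over the target.

    ``gamma`` is a Grueneisen-like proportionality constant in relative
    units; the absorber is perturbative (the fluence volume is computed for
    the absorber-free medium).
    """
    mask = absorber_mask(fluence.grid, absorber)
    return float(gamma * absorber.mu_a_absorber * fluence.nfr[mask].mean())


@dataclass
class PAFieldMap:
    """Relative PA amplitude over (lateral position, depth), dB re maximum."""

    lateral_positions: np.ndarray
    depths: np.ndarray
    amplitude_db: np.ndarray  # shape (n_lateral, n_depth)
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.lateral_positions = np.asarray(self.lateral_positions, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        self.amplitude_db = np.asarray(self.amplitude_db, dtype=float)
        if self.amplitude_db.shape != (
            self.lateral_positions.size,
            self.depths.size,
        ):
            raise ValueError("amplitude_db shape mismatch")
        finite = self.amplitude_db[np.isfinite(self.amplitude_db)]
        if finite.size and not math.isclose(float(finite.max()), 0.0, abs_tol=1e-9):
            raise ValueError("amplitude_db must be normalized to a 0 dB maximum")

    def on_axis(self) -> np.ndarray:
        """Amplitude (dB) vs depth at the lateral position nearest the axis."""
        i = int(np.argmin(np.abs(self.lateral_positions)))
        return self.amplitude_db[i, :]

    def to_frame(self) -> pd.DataFrame:
        lat, dep = np.meshgrid(self.lateral_positions, self.depths, indexing="ij")
        return pd.DataFrame(
            {
                "lateral_mm": lat.ravel(),
                "depth_mm": dep.ravel(),
                "amplitude_db": self.amplitude_db.ravel(),
            }
        )


def field_map(
    medium: VoxelGrid,
    layout,
    absorber_template: AbsorberSpec,
    lateral_positions,
    depths,
    photons_per_fiber: int = 1000,
    seed: int = 0,
    gamma: float = 1.0,
    fluence: FluenceVolume | None = None,
) -> PAFieldMap:
    """PA amplitude map of a movable absorber in an absorber-free medium.

    Runs one transport simulation of the medium (or reuses ``fluence``),
    then evaluates the perturbative amplitude with the template absorber
    placed at every (lateral, depth) position; lateral displacement is
    applied along x for line absorbers oriented along y and vice versa
    (default template orientation 'x' displaces along y).  Amplitudes are
    normalized to the map maximum and expressed as 20*log10(A / A_max) dB.
    """
    from .transport import simulate

    if fluence is None:
        fluence = simulate(medium, layout, photons_per_fiber=photons_per_fiber,
                           seed=seed)
    lateral_positions = np.asarray(lateral_positions, dtype=float)
    depths = np.asarray(depths, dtype=float)
    lateral_axis = "y" if absorber_template.orientation == "x" else "x"
    amp = np.zeros((lateral_positions.size, depths.size))
    for i, lat in enumerate(lateral_positions):
        for j, dep in enumerate(depths):
            pos = [0.0, 0.0, float(dep)]
            pos[0 if lateral_axis == "x" else 1] = float(lat)
            spec = AbsorberSpec(
                geometry=absorber_template.geometry,
                size=absorber_template.size,
                position=tuple(pos),
                orientation=absorber_template.orientation,
                mu_a_absorber=absorber_template.mu_a_absorber,
                label=absorber_template.label,
            )
            amp[i, j] = pa_amplitude_at(fluence, spec, gamma=gamma)
    a_max = amp.max()
    if a_max <= 0:
        raise ValueError("field map is entirely zero; cannot normalize")
    with np.errstate(divide="ignore"):
        amp_db = 20.0 * np.log10(amp / a_max)
    return PAFieldMap(
        lateral_positions=lateral_positions,
        depths=depths,
        amplitude_db=amp_db,
        gamma=gamma,
    )


def penetration_depth(
    pa_map: PAFieldMap, threshold_db: float
) -> tuple[float, bool]:
    """Greatest on-axis depth with amplitude >= ``threshold_db``.

    Linearly interpolates between sampled depths at the last downward
    threshold crossing.  Returns ``(depth_mm, crossed)``; if the on-axis
    curve never falls below the threshold, the maximum sampled depth is
    returned with ``crossed = False``.
    """
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative")
    curve = pa_map.on_axis()
    depths = pa_map.depths
    above = curve >= threshold_db
    if not above.any():
        return float(depths[0]), False
    last = int(np.max(np.nonzero(above)))
    if last == depths.size - 1:
        return float(depths[-1]), False
    # Interpolate between the last above-threshold sample and the next one.
    d0, d1 = depths[last], depths[last + 1]
    a0, a1 = curve[last], curve[last + 1]
    if not np.isfinite(a1):
        return float(d0), True
    frac = (threshold_db - a0) / (a1 - a0)
    return float(d0 + frac * (d1 - d0)), True


def field_width(
    pa_map: PAFieldMap, threshold_db: float, depth: float
) -> tuple[float, bool]:
    """Lateral extent with amplitude >= ``threshold_db`` at a sampled depth.

    Interpolates the two outermost threshold crossings; returns
    ``(width_mm, crossed)`` with ``crossed = False`` when the whole lateral
    line stays above the threshold (width is then the full sampled span).
    """
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative")
    j = int(np.argmin(np.abs(pa_map.depths - depth)))
    if abs(pa_map.depths[j] - depth) > 1e-6 + 1e-3 * abs(depth):
        raise ValueError(f"depth {depth} mm is not sampled in the map")
    line = pa_map.amplitude_db[:, j]
    lat = pa_map.lateral_positions
    above = line >= threshold_db
    if not above.any():
        return 0.0, True
    first = int(np.min(np.nonzero(above)))
    last = int(np.max(np.nonzero(above)))
    left = lat[first]
    if first > 0 and np.isfinite(line[first - 1]):
        frac = (threshold_db - line[first]) / (line[first - 1] - line[first])
        left = lat[first] + frac * (lat[first - 1] - lat[first])
    right = lat[last]
    if last < lat.size - 1 and np.isfinite(line[last + 1]):
        frac = (threshold_db - line[last]) / (line[last + 1] - line[last])
        right = lat[last] + frac * (lat[last + 1] - lat[last])
    crossed = first > 0 and last < lat.size - 1
    return float(right - left), crossed
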