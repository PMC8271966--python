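"""Plot helpers: homogeneity curves and PA field maps.

Thin matplotlib wrappers used by the CLI; figures are saved, never shown.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .homogeneity import DepthProfile
from .pa import PAFieldMap

__all__ = ["plot_profiles", "plot_field_map", "plot_slice"]


def plot_profiles(profiles: list[DepthProfile], path: str | Path) -> Path:
    """NFR_rel vs depth, one curve per configuration."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for profile in profiles:
        ax.plot(profile.depths, profile.nfr_rel, marker="o", markersize=2,
                label=profile.config_label or None)
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel("NFR$_{rel}$ (%)")
    ax.set_ylim(0, 100)
    if any(p.config_label for p in profiles):
        ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_field_map(pa_map: PAFieldMap, path: str | Path,
                   floor_db: float = -40.0) -> Path:
    """Lateral-position x depth dB map with the display floor clipped."""
    fig, ax = plt.subplots(figsize=(5, 4))
    data = np.clip(pa_map.amplitude_db, floor_db, 0.0)
    mesh = ax.pcolormesh(pa_map.depths, pa_map.lateral_positions, data,
                         shading="nearest", cmap="inferno",
                         vmin=floor_db, vmax=0.0)
    fig.colorbar(mesh, ax=ax, label="relative PA amplitude (dB)")
    ax.set_xlabel("depth from probe (mm)")
    ax.set_ylabel("lateral position (mm)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_slice(slice_2d: np.ndarray, extent_mm: tuple[float, float],
               path: str | Path, dynamic_range_db: float | None = None) -> Path:
    """A transverse fluence/image slice; optional dB display compression."""
    fig, ax = plt.subplots(figsize=(4, 4))
    data = np.asarray(slice_2d, dtype=float)
    if dynamic_range_db is not None:
        peak = data.max()
        if peak <= 0:
            raise ValueError("cannot display an all-zero slice in dB")
        with np.errstate(divide="ignore"):
            data = np.clip(20.0 * np.log10(data / peak), -dynamic_range_db, 0.0)
    half_x, half_y = extent_mm[0] / 2.0, extent_mm[1] / 2.0
    img = ax.imshow(data.T, origin="lower", cmap="viridis",
                    extent=(-half_x, half_x, -half_y, half_y))
    fig.colorbar(img, ax=ax)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
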