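"""Run configuration: YAML-serializable description of a complete run.

A :class:`RunConfig` captures everything needed to reproduce a simulation
bit-identically: the medium (a named liver preset or explicit per-region
properties), the fiber layout, photon counts, the RNG seed, and the
analysis options (ROI side, depth-bin width, dB thresholds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grid import DEFAULT_EXTENT_MM, DEFAULT_VOXEL_MM, VoxelGrid, homogeneous_grid
from .homogeneity import DEFAULT_BIN_WIDTH_MM, DEFAULT_ROI_SIDE_MM, DEFAULT_Z_MIN_MM
from .optics import OpticalProperties, properties_from_mapping, table_properties
from .probe import (
    DEFAULT_N_FIBERS,
    DEFAULT_RING_RADIUS_MM,
    ProbeLayout,
    annular_layout,
    surface_layout,
)

__all__ = ["RunConfig", "load_config", "build_grid", "build_layout"]


@dataclass
class RunConfig:
    """Full description of one simulation + analysis run."""

    medium: dict = field(
        default_factory=lambda: {"preset": "native", "wavelength": 650}
    )
    extent: tuple[float, float, float] = DEFAULT_EXTENT_MM
    voxel_size: float = DEFAULT_VOXEL_MM
    layout: dict = field(
        default_factory=lambda: {
            "kind": "annular",
            "n_fibers": DEFAULT_N_FIBERS,
            "ring_radius": DEFAULT_RING_RADIUS_MM,
        }
    )
    photons_per_fiber: int = 100_000
    seed: int = 0
    output_dir: str = "."
    roi_side: float = DEFAULT_ROI_SIDE_MM
    bin_width: float = DEFAULT_BIN_WIDTH_MM
    z_min: float = DEFAULT_Z_MIN_MM
    penetration_threshold_db: float = -20.0
    width_threshold_db: float = -35.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent"] = list(self.extent)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the configuration (embedded in outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration, validating unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "extent" in data:
        data["extent"] = tuple(float(v) for v in data["extent"])
    return RunConfig(**data)


def _resolve_properties(medium: dict) -> dict[int, OpticalProperties]:
    """Medium block -> region label -> properties.

    Either ``{"preset": "native"|"ablated_70C", "wavelength": nm}`` or
    ``{"regions": {name: {mu_a, mu_s_prime, g, n}}}`` (labels assigned in
    sorted name order).
    """
    if "preset" in medium:
        props = table_properties(medium["preset"], int(medium["wavelength"]))
        return {0: props}
    if "regions" in medium:
        out = {}
        for label, (name, block) in enumerate(sorted(medium["regions"].items())):
            try:
                out[label] = properties_from_mapping(block)
            except KeyError as exc:
                raise ValueError(
                    f"region {name!r} is missing property {exc}"
                ) from exc
        return out
    raise ValueError("medium must contain either 'preset' or 'regions'")


def build_grid(config: RunConfig) -> VoxelGrid:
    """Materialize the configured medium as a homogeneous voxel grid."""
    props = _resolve_properties(config.medium)
    if len(props) != 1:
        raise ValueError(
            "multi-region media require an explicit region map; build the "
            "grid through afplight.synthetic instead"
        )
    return homogeneous_grid(
        props[0], extent=config.extent, voxel_size=config.voxel_size
    )


def build_layout(config: RunConfig) -> ProbeLayout:
    spec = dict(config.layout)
    kind = spec.pop("kind", "annular")
    if kind == "annular":
        return annular_layout(**spec)
    if kind == "surface":
        return surface_layout(**spec)
    raise ValueError(f"unknown layout kind {kind!r}")
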