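"""Volume I/O: fluence volumes as NIfTI with mm spacing plus JSON metadata.

A saved run consists of ``<prefix>.nii`` (the NFR volume, voxel spacing in
the header), ``<prefix>_regions.nii`` (the region-label map) and
``<prefix>.json`` (weights, seed, photon counts, region properties and the
configuration hash), which together reconstruct the FluenceVolume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import FluenceVolume, VoxelGrid
from .optics import OpticalProperties

__all__ = ["save_fluence", "load_fluence"]


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def save_fluence(vol: FluenceVolume, prefix: str | Path,
                 extra_meta: dict | None = None) -> Path:
    """Write a fluence volume; returns the path of the JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(vol.grid.voxel_size)
    nib.save(nib.Nifti1Image(vol.nfr.astype(np.float32), aff),
             str(prefix) + ".nii")
    nib.save(
        nib.Nifti1Image(vol.grid.region_map.astype(np.int16), aff),
        str(prefix) + "_regions.nii",
    )
    meta = {
        "extent_mm": list(vol.grid.extent),
        "voxel_size_mm": vol.grid.voxel_size,
        "region_properties": {
            str(label): props.as_dict()
            for label, props in vol.grid.region_properties.items()
        },
        "launched_weight": vol.launched_weight,
        "deposited_weight": vol.deposited_weight,
        "escaped_weight": vol.escaped_weight,
        "conservation_residual": vol.conservation_residual(),
        "seed": vol.seed,
        "photons_per_fiber": vol.photons_per_fiber,
        "n_fibers": vol.n_fibers,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = Path(str(prefix) + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=float))
    return sidecar


def load_fluence(prefix: str | Path) -> FluenceVolume:
    """Reconstruct a FluenceVolume saved by :func:`save_fluence`."""
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    nfr = np.asarray(
        nib.load(str(prefix) + ".nii").get_fdata(), dtype=np.float64
    )
    regions = np.asarray(
        nib.load(str(prefix) + "_regions.nii").get_fdata(), dtype=np.int32
    )
    props = {
        int(label): OpticalProperties(
            mu_a=block["mu_a"],
            mu_s_prime=block["mu_s_prime"],
            g=block["g"],
            n=block["n"],
            wavelength=block.get("wavelength", float("nan")),
        )
        for label, block in meta["region_properties"].items()
    }
    grid = VoxelGrid(
        extent=tuple(meta["extent_mm"]),
        voxel_size=float(meta["voxel_size_mm"]),
        region_map=regions,
        region_properties=props,
    )
    return FluenceVolume(
        grid=grid,
        nfr=nfr,
        launched_weight=meta["launched_weight"],
        deposited_weight=meta["deposited_weight"],
        escaped_weight=meta["escaped_weight"],
        seed=int(meta["seed"]),
        photons_per_fiber=int(meta["photons_per_fiber"]),
        n_fibers=int(meta["n_fibers"]),
    )
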