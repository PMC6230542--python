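"""Volume, sinogram, config and slice-dataset persistence.

All image volumes go through NIfTI with the voxel spacing carried in
the affine; sinograms get a JSON sidecar with their scan geometry;
slice-pair datasets are HDF5 stacks; configs round-trip through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from pseudoct.physics import ScanGeometry, Sinogram
from pseudoct.preprocess import SlicePair

__all__ = [
    "save_volume",
    "load_volume",
    "save_sinogram",
    "load_sinogram",
    "save_slice_pairs",
    "load_slice_pairs",
    "load_yaml",
    "dump_yaml",
]


def save_volume(voxels: np.ndarray, spacing: tuple[float, float, float],
                path: str | Path) -> None:
    """Write a (rows, cols, slices) volume as NIfTI with spacing in the affine."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float64), spacing


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    path = Path(path)
    save_volume(sino.counts, (1.0, 1.0, 1.0), path)
    sidecar = {
        "n_angles": sino.geometry.n_angles,
        "n_bins": sino.geometry.n_bins,
        "bin_width": sino.geometry.bin_width,
        "noise_realized": sino.noise_realized,
        "seed": sino.seed,
        "count_scale": sino.count_scale,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    counts, _ = load_volume(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    geom = ScanGeometry(n_angles=meta["n_angles"], n_bins=meta["n_bins"],
                        bin_width=meta["bin_width"])
    return Sinogram(counts=counts, geometry=geom,
                    noise_realized=meta["noise_realized"], seed=meta["seed"],
                    count_scale=meta.get("count_scale", 1.0))


def save_slice_pairs(pairs: list[SlicePair], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=np.stack([p.input_slice for p in pairs]))
        f.create_dataset("targets", data=np.stack([p.target_slice for p in pairs]))
        f.create_dataset("crop_boxes", data=np.array([p.crop_box for p in pairs]))
        f.create_dataset("slice_index", data=np.array([p.slice_index for p in pairs]))
        ids = [p.source_id.encode() for p in pairs]
        f.create_dataset("source_id", data=np.array(ids, dtype="S64"))


def load_slice_pairs(path: str | Path) -> list[SlicePair]:
    with h5py.File(path, "r") as f:
        inputs = f["inputs"][...]
        targets = f["targets"][...]
        boxes = f["crop_boxes"][...]
        slice_idx = f["slice_index"][...]
        ids = [s.decode() for s in f["source_id"][...]]
    return [SlicePair(input_slice=inputs[i], target_slice=targets[i],
                      crop_box=tuple(int(v) for v in boxes[i]),
                      source_id=ids[i], slice_index=int(slice_idx[i]))
            for i in range(inputs.shape[0])]


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)
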