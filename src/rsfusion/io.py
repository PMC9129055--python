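"""NIfTI-1 and table I/O for cohorts, masks and activity maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .measures import ActivityMap
from .preprocess import BrainMask
from .volume import BoldVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_map",
    "save_cohort",
    "load_cohort",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def save_volume(volume: BoldVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_zooms((*volume.voxel_size_mm, volume.tr_seconds))
    nib.save(img, str(path))


def load_volume(path) -> BoldVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return BoldVolume(np.asarray(img.dataobj, dtype=float), tuple(float(z) for z in zooms[:3]), tr)


def save_mask(mask: BrainMask, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(np.asarray(img.dataobj) > 0)


def save_map(amap: ActivityMap, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    img = nib.Nifti1Image(amap.data.astype(np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))


def save_cohort(cohort, out_dir) -> None:
    """Write one 4D NIfTI per subject plus a labels table (subject_id,label)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (volume, label) in enumerate(cohort):
        sid = f"sub-{i:04d}"
        save_volume(volume, out_dir / f"{sid}_bold.nii.gz")
        rows.append({"subject_id": sid, "label": label})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)


def load_cohort(in_dir) -> list[tuple[BoldVolume, str]]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "labels.csv")
    cohort = []
    for _, row in table.iterrows():
        volume = load_volume(in_dir / f"{row.subject_id}_bold.nii.gz")
        cohort.append((volume, str(row.label)))
    return cohort
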