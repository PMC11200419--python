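"""NIfTI persistence for paired studies and datasets.

A study is a directory of ``.nii.gz`` volumes plus a JSON sidecar carrying
the study id, generator seed and voxel spacing; a dataset is a directory of
study directories with a manifest.  Round-trips are exact for the float
volumes and the integer masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import PairedStudy, Volume

__all__ = ["save_study", "load_study", "save_dataset", "load_dataset"]

_FLOAT_FILES = {
    "conditioning": "conditioning.nii.gz",
    "target": "target.nii.gz",
    "healthy_target": "healthy.nii.gz",
    "lesion_field": "lesion_field.nii.gz",
}
_MASK_FILES = {"bone_mask": "bone.nii.gz", "lesion_truth": "lesion.nii.gz"}


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def _write(vol: Volume, path: Path, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), _affine(vol.spacing))
    nib.save(img, str(path))


def _read(path: Path, spacing, orientation: str) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.get_fdata(), dtype=np.float64), tuple(spacing), orientation)


def save_study(study: PairedStudy, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FLOAT_FILES.items():
        _write(getattr(study, attr), d / fname, np.float64)
    for attr, fname in _MASK_FILES.items():
        _write(getattr(study, attr), d / fname, np.uint8)
    for k, mask in enumerate(study.rater_masks):
        _write(mask, d / f"rater_{k}.nii.gz", np.uint8)
    meta = {
        "study_id": study.study_id,
        "seed": study.seed,
        "spacing": list(study.target.spacing),
        "orientation": study.target.orientation,
        "n_raters": len(study.rater_masks),
    }
    (d / "study.json").write_text(json.dumps(meta, indent=2))
    return d


def load_study(directory: str | Path) -> PairedStudy:
    d = Path(directory)
    meta = json.loads((d / "study.json").read_text())
    spacing, orient = meta["spacing"], meta["orientation"]
    vols = {attr: _read(d / f, spacing, orient) for attr, f in _FLOAT_FILES.items()}
    masks = {}
    for attr, f in _MASK_FILES.items():
        v = _read(d / f, spacing, orient)
        masks[attr] = v.with_data(v.data.astype(np.uint8))
    raters = []
    for k in range(meta["n_raters"]):
        v = _read(d / f"rater_{k}.nii.gz", spacing, orient)
        raters.append(v.with_data(v.data.astype(np.uint8)))
    return PairedStudy(
        conditioning=vols["conditioning"],
        target=vols["target"],
        bone_mask=masks["bone_mask"],
        lesion_truth=masks["lesion_truth"],
        rater_masks=raters,
        healthy_target=vols["healthy_target"],
        lesion_field=vols["lesion_field"],
        study_id=meta["study_id"],
        seed=int(meta["seed"]),
    )


def save_dataset(studies, root: str | Path) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for study in studies:
        save_study(study, root / study.study_id)
        entries.append({"study_id": study.study_id, "seed": study.seed,
                        "has_lesions": bool(study.lesion_truth.data.any())})
    (root / "manifest.json").write_text(json.dumps({"studies": entries}, indent=2))
    return root


def load_dataset(root: str | Path) -> list[PairedStudy]:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    return [load_study(root / e["study_id"]) for e in manifest["studies"]]
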