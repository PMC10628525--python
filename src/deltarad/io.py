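"""NIfTI-1 and manifest I/O for cohorts, feature tables and results.

Volumes and masks are written as NIfTI with voxel spacing encoded in a
diagonal affine (origin in the translation column).  A cohort manifest CSV
records one row per subject with paths per time point and reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import TIMEPOINTS, ImageVolume, RoiMask, SubjectRecord, TimepointData

PathLike = Union[str, Path]


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def save_volume(volume: ImageVolume, path: PathLike) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def load_volume(path: PathLike) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)


def save_mask(mask: RoiMask, volume: ImageVolume, path: PathLike) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def load_mask(path: PathLike) -> RoiMask:
    img = nib.load(str(path))
    return RoiMask(np.asarray(img.dataobj) > 0)


def write_cohort(cohort: Sequence[SubjectRecord], outdir: PathLike) -> Path:
    """Write per-subject NIfTI files and a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: List[Dict[str, str]] = []
    for rec in cohort:
        subj_dir = outdir / rec.subject_id
        subj_dir.mkdir(exist_ok=True)
        row: Dict[str, str] = {"subject_id": rec.subject_id, "response": rec.response}
        for tp in TIMEPOINTS:
            td = rec.timepoints[tp]
            vol_path = subj_dir / f"{tp}_volume.nii.gz"
            mask_path = subj_dir / f"{tp}_tumor_mask.nii.gz"
            save_volume(td.volume, vol_path)
            save_mask(td.tumor_mask, td.volume, mask_path)
            row[f"volume_{tp}"] = str(vol_path.relative_to(outdir))
            row[f"mask_{tp}"] = str(mask_path.relative_to(outdir))
            if td.bed_mask is not None:
                bed_path = subj_dir / f"{tp}_bed_mask.nii.gz"
                save_mask(td.bed_mask, td.volume, bed_path)
                row[f"bed_mask_{tp}"] = str(bed_path.relative_to(outdir))
            if rec.reader2_masks is not None and tp in rec.reader2_masks:
                p = subj_dir / f"{tp}_reader2_mask.nii.gz"
                save_mask(rec.reader2_masks[tp], td.volume, p)
                row[f"reader2_mask_{tp}"] = str(p.relative_to(outdir))
            if rec.reader1_repeat_masks is not None and tp in rec.reader1_repeat_masks:
                p = subj_dir / f"{tp}_reader1_repeat_mask.nii.gz"
                save_mask(rec.reader1_repeat_masks[tp], td.volume, p)
                row[f"repeat_mask_{tp}"] = str(p.relative_to(outdir))
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: PathLike) -> List[SubjectRecord]:
    """Read a manifest CSV back into SubjectRecords; errors name the subject."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype=str)
    cohort: List[SubjectRecord] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        timepoints: Dict[str, TimepointData] = {}
        for tp in TIMEPOINTS:
            for key in (f"volume_{tp}", f"mask_{tp}"):
                if key not in row or pd.isna(row[key]):
                    raise ValueError(f"subject {sid}: manifest is missing {key}")
                if not (root / row[key]).exists():
                    raise FileNotFoundError(f"subject {sid}: {row[key]} does not exist")
            volume = load_volume(root / row[f"volume_{tp}"])
            tumor = load_mask(root / row[f"mask_{tp}"])
            bed: Optional[RoiMask] = None
            bed_key = f"bed_mask_{tp}"
            if bed_key in row and isinstance(row.get(bed_key), str):
                bed = load_mask(root / row[bed_key])
            timepoints[tp] = TimepointData(volume, tumor, bed_mask=bed)

        def _optional_masks(prefix: str) -> Optional[Dict[str, RoiMask]]:
            masks = {}
            for tp in TIMEPOINTS:
                key = f"{prefix}_{tp}"
                if key in row and isinstance(row.get(key), str):
                    masks[tp] = load_mask(root / row[key])
            return masks or None

        cohort.append(
            SubjectRecord(
                subject_id=sid,
                response=row["response"],
                timepoints=timepoints,
                reader2_masks=_optional_masks("reader2_mask"),
                reader1_repeat_masks=_optional_masks("repeat_mask"),
            )
        )
    return cohort
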