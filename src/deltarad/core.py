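"""Core domain types shared across the pipeline.

All physical quantities are expressed in millimetres.  Voxel indices are
0-based; image grids are plain 3D numpy arrays with an associated voxel
spacing (and, for NIfTI round-trips, an origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

TIMEPOINTS: Tuple[str, str, str] = ("BL", "C2", "C4")
DELTA_PAIRS: Tuple[Tuple[str, str, str], ...] = (
    ("C2BL", "C2", "BL"),
    ("C4BL", "C4", "BL"),
    ("C4C2", "C4", "C2"),
)
REGIONS: Tuple[str, str] = ("Peritumoral", "Tumoral")

#: Column-name prefix per region.  The tumoral region is printed as
#: ``Tumor`` in per-feature names but as ``Tumoral`` in model names.
REGION_PREFIX: Mapping[str, str] = {"Peritumoral": "Peritumoral", "Tumoral": "Tumor"}

PCR = "pCR"
NON_PCR = "non-pCR"


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data :
        3D array of finite intensities.
    spacing :
        Voxel edge lengths in mm, one per axis, all strictly positive.
    origin :
        World-space position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={data.ndim}")
        if any(s < 8 for s in data.shape):
            raise ValueError(f"volume must be at least 8 voxels per axis, got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must all be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class RoiMask:
    """Binary 3D mask annotating an :class:`ImageVolume` grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={data.ndim}")
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass
class TimepointData:
    """Volume plus segmentations at one imaging time point.

    ``tumor_mask`` is the enhancing-tumor segmentation and may be empty at
    follow-up time points; ``bed_mask`` is the fallback tumor-bed
    segmentation used for feature extraction when no enhancement remains.
    """

    volume: ImageVolume
    tumor_mask: RoiMask
    bed_mask: Optional[RoiMask] = None

    def effective_mask(self) -> RoiMask:
        """Mask used for feature extraction: tumor if nonempty, else bed."""
        if not self.tumor_mask.is_empty():
            return self.tumor_mask
        if self.bed_mask is not None:
            return self.bed_mask
        return self.tumor_mask

    def _validate(self) -> None:
        if self.tumor_mask.shape != self.volume.shape:
            raise ValueError("tumor mask shape differs from volume shape")
        if self.bed_mask is not None and self.bed_mask.shape != self.volume.shape:
            raise ValueError("bed mask shape differs from volume shape")


@dataclass
class SubjectRecord:
    """One subject: response label plus per-time-point imaging."""

    subject_id: str
    response: str
    timepoints: Dict[str, TimepointData]
    reader2_masks: Optional[Dict[str, RoiMask]] = None
    reader1_repeat_masks: Optional[Dict[str, RoiMask]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response not in (PCR, NON_PCR):
            raise ValueError(f"response must be {PCR!r} or {NON_PCR!r}, got {self.response!r}")
        missing = [tp for tp in TIMEPOINTS if tp not in self.timepoints]
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing time points {missing}")
        if self.timepoints["BL"].tumor_mask.is_empty():
            raise ValueError(f"subject {self.subject_id}: BL tumor mask is empty")
        for tp in TIMEPOINTS:
            self.timepoints[tp]._validate()
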