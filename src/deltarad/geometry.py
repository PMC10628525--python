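"""Peritumoral ROI construction by fixed-thickness physical expansion.

Distances are centre-to-centre Euclidean distances in physical mm, computed
with a spacing-aware distance transform, so anisotropic grids (e.g. 3 mm
slices with sub-mm in-plane resolution) expand correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import RoiMask

DEFAULT_THICKNESS_MM = 10.0


@dataclass(frozen=True)
class PeritumoralSpec:
    """Physical thickness of the peritumoral shell (mm)."""

    thickness_mm: float = DEFAULT_THICKNESS_MM

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(f"thickness_mm must be > 0, got {self.thickness_mm}")


def distance_from_mask(mask: RoiMask, spacing: Sequence[float]) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest in-mask voxel centre.

    In-mask voxels have distance 0.  Raises ``ValueError`` on an empty mask.
    """
    if mask.is_empty():
        raise ValueError("distance_from_mask: mask is empty")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
    return ndimage.distance_transform_edt(~mask.data, sampling=spacing)


def peritumoral_ring(
    tumor: RoiMask,
    spacing: Sequence[float],
    spec: PeritumoralSpec = PeritumoralSpec(),
) -> RoiMask:
    """Shell of voxels within ``spec.thickness_mm`` of the tumor, excluding it.

    The upper bound is closed: voxels at exactly ``thickness_mm`` are
    included.  The ring is implicitly clipped to the image grid.  An empty
    tumor mask yields an empty ring with a warning (covers the absent
    tumor-bed edge case).
    """
    if tumor.is_empty():
        warnings.warn("peritumoral_ring: empty tumor mask, returning empty ring", stacklevel=2)
        return RoiMask(np.zeros(tumor.shape, dtype=bool))
    dist = distance_from_mask(tumor, spacing)
    ring = (dist > 0) & (dist <= spec.thickness_mm)
    return RoiMask(ring)
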