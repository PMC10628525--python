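"""Per-ROI extraction of the 310-feature set (10 FO + 300 GLCM).

For each gray-level setting in :data:`~deltarad.glcm.GRAY_LEVELS`, the
in-ROI intensities are quantized, one GLCM is built per canonical 3D
direction, each of the 20 scalars is computed per direction, and the
per-direction values are reduced to (mean, range, angular variance):
20 x 3 = 60 rotation-invariant features per gray level, 300 in total.

Feature naming follows ``<Region>_DCE_<Block>_<FO|GLCM>_<Name>`` with
``Percentile.N`` dots for first-order percentiles and
``GLCM_<Name>_N<levels>_<Mean|Range|AngularVariance>`` for texture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .core import REGION_PREFIX, ImageVolume, RoiMask
from .firstorder import FO_NAMES, first_order_features
from .glcm import (
    AGGREGATE_NAMES,
    DIRECTIONS,
    GLCM_SCALAR_NAMES,
    GRAY_LEVELS,
    glcm_matrix,
    glcm_scalar_features,
    quantize_roi,
    rotation_invariant_aggregate,
)

logger = logging.getLogger(__name__)

#: Fingerprint of the extraction conventions, emitted alongside features.
CONVENTIONS_FINGERPRINT = (
    "glcm3d-13dir-dist1-sym;quant-minmax-equalwidth;log2;"
    "percentile-linear;sd-ddof1;skew-adj;kurt-pearson;angvar-ddof0"
)


def feature_local_names(gray_levels: Sequence[int] = GRAY_LEVELS) -> Tuple[str, ...]:
    """The 310 feature names without the region/time-point prefix."""
    names = [f"FO_{n}" for n in FO_NAMES]
    for g in gray_levels:
        for scalar in GLCM_SCALAR_NAMES:
            for agg in AGGREGATE_NAMES:
                names.append(f"GLCM_{scalar}_N{g}_{agg}")
    return tuple(names)


def full_feature_name(region: str, block: str, local_name: str) -> str:
    """Render the published column name, e.g. ``Tumor_DCE_RD-C4BL_FO_Mean``."""
    return f"{REGION_PREFIX[region]}_DCE_{block}_{local_name}"


@dataclass
class FeatureVector:
    """310 named feature values for one (subject, region, time point)."""

    values: Dict[str, float]
    region: str
    timepoint_or_delta: str
    n_voxels: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = feature_local_names()
        if tuple(self.values.keys()) != expected:
            raise ValueError(
                f"feature vector must have exactly the {len(expected)} canonical names in order"
            )

    def full_names(self) -> Tuple[str, ...]:
        return tuple(
            full_feature_name(self.region, self.timepoint_or_delta, n) for n in self.values
        )


def extract_features(
    volume: ImageVolume,
    mask: RoiMask,
    region: str = "Tumoral",
    timepoint: str = "BL",
    gray_levels: Sequence[int] = GRAY_LEVELS,
) -> FeatureVector:
    """Extract the 310 features of ``volume`` restricted to ``mask``.

    An empty mask yields 310 missing values with a logged warning (the
    enhancement-free tumor-bed case).
    """
    if mask.shape != volume.shape:
        raise ValueError("mask is not on the volume's grid")
    names = feature_local_names(gray_levels)
    if mask.is_empty():
        logger.warning("extract_features: empty mask (%s %s) -> all features missing",
                       region, timepoint)
        return FeatureVector({n: math.nan for n in names}, region, timepoint, n_voxels=0)

    inroi = volume.data[mask.data]
    values: Dict[str, float] = {}
    for fo_name, v in first_order_features(inroi).items():
        values[f"FO_{fo_name}"] = v

    for g in gray_levels:
        levels = np.zeros(volume.shape, dtype=np.int64)
        levels[mask.data] = quantize_roi(inroi, g)
        per_dir = {scalar: [] for scalar in GLCM_SCALAR_NAMES}
        for offset in DIRECTIONS:
            P = glcm_matrix(levels, mask, offset, g)
            for scalar, v in glcm_scalar_features(P).items():
                per_dir[scalar].append(v)
        for scalar in GLCM_SCALAR_NAMES:
            mean, rng, angvar = rotation_invariant_aggregate(per_dir[scalar])
            values[f"GLCM_{scalar}_N{g}_Mean"] = mean
            values[f"GLCM_{scalar}_N{g}_Range"] = rng
            values[f"GLCM_{scalar}_N{g}_AngularVariance"] = angvar

    assert tuple(values.keys()) == names
    return FeatureVector(
        values,
        region,
        timepoint,
        n_voxels=mask.n_voxels,
        meta={"conventions": CONVENTIONS_FINGERPRINT},
    )
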