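"""Absolute/relative delta features across time-point pairs and the wide
longitudinal feature table.

AD = late - early.  RD = (late - early) / |early|, with RD = 0 when both
values are 0 and missing when early = 0 != late; the absolute-value
denominator keeps the sign of RD aligned with the direction of change for
negative-valued features.  RD is reported as a fraction (not x100).
Missing values propagate (pairwise deletion downstream).
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DELTA_PAIRS, REGIONS, TIMEPOINTS, SubjectRecord
from .features import FeatureVector, feature_local_names, full_feature_name

logger = logging.getLogger(__name__)

#: Column blocks per region, in table order.
BLOCKS: Tuple[str, ...] = (
    "BL",
    "C2",
    "C4",
    "AD-C2BL",
    "AD-C4BL",
    "AD-C4C2",
    "RD-C2BL",
    "RD-C4BL",
    "RD-C4C2",
)


def _check_names(f_late: FeatureVector, f_early: FeatureVector) -> None:
    mism = [n for n in f_late.values if n not in f_early.values]
    mism += [n for n in f_early.values if n not in f_late.values]
    if mism:
        raise ValueError(f"feature name mismatch: {sorted(set(mism))[:5]} ...")
    if f_late.region != f_early.region:
        raise ValueError(f"region mismatch: {f_late.region} vs {f_early.region}")


def absolute_difference(f_late: FeatureVector, f_early: FeatureVector, pair: str) -> FeatureVector:
    """Per-feature late - early; missing if either input is missing."""
    _check_names(f_late, f_early)
    values = {n: f_late.values[n] - f_early.values[n] for n in f_late.values}
    return FeatureVector(values, f_late.region, f"AD-{pair}")


def _rd(late: float, early: float) -> float:
    if math.isnan(late) or math.isnan(early):
        return math.nan
    if early == 0.0:
        return 0.0 if late == 0.0 else math.nan
    return (late - early) / abs(early)


def relative_difference(f_late: FeatureVector, f_early: FeatureVector, pair: str) -> FeatureVector:
    """Per-feature (late - early) / |early| (fractional change)."""
    _check_names(f_late, f_early)
    values = {n: _rd(f_late.values[n], f_early.values[n]) for n in f_late.values}
    return FeatureVector(values, f_late.region, f"RD-{pair}")


def longitudinal_blocks(
    per_timepoint: Mapping[str, FeatureVector],
) -> Dict[str, FeatureVector]:
    """Expand {BL, C2, C4} feature vectors into all 9 blocks for one region."""
    out: Dict[str, FeatureVector] = {tp: per_timepoint[tp] for tp in TIMEPOINTS}
    for pair, late, early in DELTA_PAIRS:
        out[f"AD-{pair}"] = absolute_difference(per_timepoint[late], per_timepoint[early], pair)
        out[f"RD-{pair}"] = relative_difference(per_timepoint[late], per_timepoint[early], pair)
    return out


def table_columns(regions: Sequence[str] = REGIONS) -> List[str]:
    """Full ordered column list: per region, 9 blocks x 310 features."""
    cols: List[str] = []
    local = feature_local_names()
    for region in regions:
        for block in BLOCKS:
            cols.extend(full_feature_name(region, block, n) for n in local)
    return cols


def assemble_longitudinal_table(
    cohort: Sequence[SubjectRecord],
    features: Mapping[str, Mapping[str, Mapping[str, FeatureVector]]],
) -> pd.DataFrame:
    """Build the wide subjects x features table with a ``response`` column.

    ``features[subject_id][region][timepoint]`` holds the per-time-point
    extraction for that subject/region.  A missing time point keeps the row
    and leaves the affected columns missing, with a warning.
    """
    cols = table_columns()
    rows = []
    index = []
    labels = []
    local = feature_local_names()
    for rec in cohort:
        per_subj = features.get(rec.subject_id, {})
        row: Dict[str, float] = {}
        for region in REGIONS:
            per_tp = per_subj.get(region, {})
            missing_tps = [tp for tp in TIMEPOINTS if tp not in per_tp]
            if missing_tps:
                logger.warning(
                    "subject %s region %s: missing time points %s; columns left missing",
                    rec.subject_id, region, missing_tps,
                )
                nanvec = {n: math.nan for n in local}
                per_tp = dict(per_tp)
                for tp in missing_tps:
                    per_tp[tp] = FeatureVector(dict(nanvec), region, tp)
            blocks = longitudinal_blocks(per_tp)
            for block in BLOCKS:
                fv = blocks[block]
                for n, v in fv.values.items():
                    row[full_feature_name(region, block, n)] = v
        rows.append(row)
        index.append(rec.subject_id)
        labels.append(rec.response)

    table = pd.DataFrame(rows, index=index, columns=cols, dtype=float)
    table.index.name = "subject_id"
    table.insert(0, "response", labels)
    return table


def feature_columns(table: pd.DataFrame) -> List[str]:
    """Feature columns of a longitudinal table (everything except the label)."""
    return [c for c in table.columns if c != "response"]
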