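"""Interreader agreement of radiomic features between two segmentation sets.

Per feature: Pearson correlation across subjects, a two-sided Wilcoxon
signed-rank test (zero differences dropped, classic convention), and an
interreader-to-intrareader variance ratio.  The variance components are
estimated from paired squared differences:

    intra = 1/2 * mean_subjects (r1 - r1_repeat)^2
    inter = max(0, 1/2 * mean_subjects (r1 - r2)^2 - intra)
    ratio = inter / Var_subjects(r1 values), with 0/0 -> 0

A lower ratio indicates greater agreement.
"""

from __future__ import annotations

import math
import re
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .deltas import feature_columns

_MIN_PAIRS = 3


def _classify_feature(name: str) -> str:
    """Feature class tag like ``original FO`` / ``RD GLCM`` from a column name."""
    family = "GLCM" if "_GLCM_" in name else "FO"
    m = re.search(r"_DCE_(AD|RD)-", name)
    kind = m.group(1) if m else "original"
    return f"{kind} {family}"


def _paired(a: pd.Series, b: pd.Series) -> Optional[np.ndarray]:
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < _MIN_PAIRS:
        return None
    return np.stack([x[keep], y[keep]])


def pearson_per_feature(table_r1: pd.DataFrame, table_r2: pd.DataFrame) -> pd.Series:
    """Product-moment correlation per feature across subjects (pairwise deletion).

    Missing (NaN) when either reader's values are constant or fewer than
    3 complete pairs remain.
    """
    cols = feature_columns(table_r1)
    out = {}
    for col in cols:
        pair = _paired(table_r1[col], table_r2[col])
        if pair is None or pair[0].std() == 0 or pair[1].std() == 0:
            out[col] = math.nan
            continue
        out[col] = float(stats.pearsonr(pair[0], pair[1]).statistic)
    return pd.Series(out, name="pearson_r")


def signed_rank_per_feature(table_r1: pd.DataFrame, table_r2: pd.DataFrame) -> pd.Series:
    """Two-sided Wilcoxon signed-rank p per feature; all-zero differences -> p = 1."""
    cols = feature_columns(table_r1)
    out = {}
    for col in cols:
        pair = _paired(table_r1[col], table_r2[col])
        if pair is None:
            out[col] = math.nan
            continue
        diff = pair[0] - pair[1]
        if np.all(diff == 0):
            out[col] = 1.0
            continue
        out[col] = float(
            stats.wilcoxon(pair[0], pair[1], zero_method="wilcox",
                           alternative="two-sided").pvalue
        )
    return pd.Series(out, name="p_signed_rank")


def variance_ratio_per_feature(
    table_r1: pd.DataFrame,
    table_r1_repeat: pd.DataFrame,
    table_r2: pd.DataFrame,
) -> pd.Series:
    """Interreader-to-cohort variance ratio per feature (clipped at 0).

    Missing when the cohort variance of the reader-1 values is 0.
    """
    cols = feature_columns(table_r1)
    out = {}
    for col in cols:
        x1 = table_r1[col].to_numpy(dtype=float)
        x1r = table_r1_repeat[col].to_numpy(dtype=float)
        x2 = table_r2[col].to_numpy(dtype=float)
        keep = np.isfinite(x1) & np.isfinite(x1r) & np.isfinite(x2)
        if keep.sum() < _MIN_PAIRS:
            out[col] = math.nan
            continue
        x1, x1r, x2 = x1[keep], x1r[keep], x2[keep]
        intra = 0.5 * float(np.mean((x1 - x1r) ** 2))
        inter = max(0.0, 0.5 * float(np.mean((x1 - x2) ** 2)) - intra)
        cohort_var = float(np.var(x1, ddof=1))
        if cohort_var == 0:
            out[col] = 0.0 if inter == 0 else math.nan
            continue
        out[col] = inter / cohort_var
    return pd.Series(out, name="variance_ratio")


def reliability_table(
    table_r1: pd.DataFrame,
    table_r2: pd.DataFrame,
    table_r1_repeat: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-feature reliability results (r, signed-rank p, variance ratio, class)."""
    r = pearson_per_feature(table_r1, table_r2)
    p = signed_rank_per_feature(table_r1, table_r2)
    df = pd.concat([r, p], axis=1)
    if table_r1_repeat is not None:
        df["variance_ratio"] = variance_ratio_per_feature(table_r1, table_r1_repeat, table_r2)
    else:
        df["variance_ratio"] = math.nan
    df["feature_class"] = [_classify_feature(c) for c in df.index]
    df.index.name = "feature"
    return df


def summarize_reliability(results: pd.DataFrame, r_threshold: float = 0.8) -> Dict[str, dict]:
    """Per feature class: fraction with r > threshold and variance-ratio stats."""
    summary: Dict[str, dict] = {}
    if len(results) == 0:
        return summary
    for cls, grp in results.groupby("feature_class"):
        r = grp["pearson_r"].dropna()
        vr = grp["variance_ratio"].dropna()
        summary[str(cls)] = {
            "n_features": int(len(grp)),
            "frac_r_above": float((r > r_threshold).mean()) if len(r) else math.nan,
            "variance_ratio_mean": float(vr.mean()) if len(vr) else math.nan,
            "variance_ratio_median": float(vr.median()) if len(vr) else math.nan,
            "variance_ratio_sd": float(vr.std(ddof=1)) if len(vr) > 1 else math.nan,
            "variance_ratio_min": float(vr.min()) if len(vr) else math.nan,
            "variance_ratio_max": float(vr.max()) if len(vr) else math.nan,
        }
    return summary
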