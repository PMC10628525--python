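"""Gray-level co-occurrence matrices and their 20 scalar summaries.

GLCMs are computed volumetrically on the 3D ROI at a fixed offset distance
of 1 voxel along each of the 13 unique 3D directions (26-connectivity
modulo sign).  Counting is symmetric (each ordered pair increments both
(i, j) and (j, i)), and matrices are normalized to sum to 1.  Entropy-type
terms use log base 2 with the convention 0*log(0) = 0.

The per-direction scalars are summarized across directions by mean, range
and angular (population) variance, producing rotation-invariant features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .core import RoiMask

#: The 13 unique offsets at Chebyshev distance 1 (one per +/- direction pair).
DIRECTIONS: Tuple[Tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GRAY_LEVELS: Tuple[int, ...] = (8, 16, 32, 64, 256)

#: The 20 scalar summaries computed from each GLCM.
GLCM_SCALAR_NAMES: Tuple[str, ...] = (
    "Autocorrelation",
    "Correlation",
    "Contrast",
    "ClusterProminence",
    "ClusterShade",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "MaximumProbability",
    "SumOfSquaresVariance",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "DifferenceVariance",
    "DifferenceEntropy",
    "IMC1",
    "IMC2",
    "InverseDifferenceNormalized",
    "InverseDifferenceMomentNormalized",
)

AGGREGATE_NAMES: Tuple[str, str, str] = ("Mean", "Range", "AngularVariance")

_LOG_BASE = 2.0


@dataclass(frozen=True)
class GlcmMatrix:
    """Normalized symmetric co-occurrence matrix for one offset direction."""

    P: np.ndarray
    n_levels: int
    offset: Tuple[int, int, int]
    empty: bool = False

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.n_levels, self.n_levels):
            raise ValueError(f"P must be {self.n_levels}x{self.n_levels}, got {P.shape}")
        object.__setattr__(self, "P", P)


def quantize_roi(intensities: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of in-ROI intensities into levels 1..n_levels.

    Bins span the in-ROI [min, max]; the maximum maps to ``n_levels`` and a
    constant ROI maps everything to level 1.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("quantize_roi: empty ROI")
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    levels = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    np.clip(levels, 1, n_levels, out=levels)
    return levels


def glcm_matrix(
    levels: np.ndarray,
    mask: RoiMask,
    offset: Sequence[int],
    n_levels: int,
) -> GlcmMatrix:
    """Symmetric normalized GLCM for one offset over in-mask voxel pairs.

    Both voxels of a counted pair must lie inside the mask.  If the offset
    admits no valid pair the matrix is flagged empty and downstream scalars
    are missing.
    """
    offset = tuple(int(o) for o in offset)
    if offset not in DIRECTIONS:
        raise ValueError(f"offset {offset} is not one of the 13 canonical directions")
    lv = np.asarray(levels)
    m = mask.data
    if lv.shape != m.shape:
        raise ValueError("levels and mask shapes differ")

    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax] = slice(0, lv.shape[ax] - d)
            dst[ax] = slice(d, lv.shape[ax])
        elif d < 0:
            src[ax] = slice(-d, lv.shape[ax])
            dst[ax] = slice(0, lv.shape[ax] + d)
    src_t, dst_t = tuple(src), tuple(dst)
    valid = m[src_t] & m[dst_t]
    a = lv[src_t][valid] - 1
    b = lv[dst_t][valid] - 1
    if a.size == 0:
        return GlcmMatrix(np.zeros((n_levels, n_levels)), n_levels, offset, empty=True)
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).astype(float)
    C = counts.reshape(n_levels, n_levels)
    C = C + C.T
    return GlcmMatrix(C / C.sum(), n_levels, offset)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_scalar_features(glcm: GlcmMatrix) -> Dict[str, float]:
    """The 20 scalar texture summaries of one normalized GLCM.

    Correlation is missing (NaN) when a marginal standard deviation is 0;
    a flagged-empty matrix yields all-NaN.  Sums are evaluated over the
    nonzero entries of P only (exact: zero entries contribute nothing).
    """
    if glcm.empty:
        return {name: math.nan for name in GLCM_SCALAR_NAMES}
    P = glcm.P
    Ng = glcm.n_levels
    ii, jj = np.nonzero(P)
    p = P[ii, jj]
    iv = ii + 1.0
    jv = jj + 1.0
    absdiff = np.abs(iv - jv)

    px = P.sum(axis=1)  # == py by symmetry
    lev = np.arange(1, Ng + 1, dtype=float)
    mu_x = float(np.sum(lev * px))
    var_x = float(np.sum((lev - mu_x) ** 2 * px))
    sd_x = math.sqrt(var_x)

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    p_sum = np.bincount((ii + jj).astype(np.int64), weights=p, minlength=2 * Ng - 1)
    ksum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_diff = np.bincount(np.abs(ii - jj).astype(np.int64), weights=p, minlength=Ng)
    kdiff = np.arange(0, Ng, dtype=float)

    sum_average = float(np.sum(ksum * p_sum))
    sum_variance = float(np.sum((ksum - sum_average) ** 2 * p_sum))
    mu_diff = float(np.sum(kdiff * p_diff))

    hxy = _entropy(p)
    lpx = np.zeros(Ng)
    pos = px > 0
    lpx[pos] = np.log2(px[pos])
    hx = float(-np.sum(px[pos] * lpx[pos]))
    # P(i,j) > 0 implies px(i) > 0 and px(j) > 0
    hxy1 = float(-np.sum(p * (lpx[ii] + lpx[jj])))
    hxy2 = float(-np.sum(np.outer(px[pos], px[pos]) * np.add.outer(lpx[pos], lpx[pos])))

    if hx > 0:
        imc1 = (hxy - hxy1) / hx  # max(HX, HY) = HX by symmetry
    else:
        imc1 = math.nan
    arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy) * math.log(_LOG_BASE))
    imc2 = math.sqrt(max(arg, 0.0))

    if sd_x > 0:
        correlation = float(np.sum((iv - mu_x) * (jv - mu_x) * p)) / (sd_x * sd_x)
    else:
        correlation = math.nan

    sumdev = iv + jv - 2 * mu_x
    out = {
        "Autocorrelation": float(np.sum(iv * jv * p)),
        "Correlation": correlation,
        "Contrast": float(np.sum((iv - jv) ** 2 * p)),
        "ClusterProminence": float(np.sum(sumdev**4 * p)),
        "ClusterShade": float(np.sum(sumdev**3 * p)),
        "Dissimilarity": float(np.sum(absdiff * p)),
        "Energy": float(np.sum(p * p)),
        "Entropy": hxy,
        "Homogeneity": float(np.sum(p / (1.0 + absdiff))),
        "MaximumProbability": float(p.max()),
        "SumOfSquaresVariance": float(np.sum((iv - mu_x) ** 2 * p)),
        "SumAverage": sum_average,
        "SumVariance": sum_variance,
        "SumEntropy": _entropy(p_sum),
        "DifferenceVariance": float(np.sum((kdiff - mu_diff) ** 2 * p_diff)),
        "DifferenceEntropy": _entropy(p_diff),
        "IMC1": imc1,
        "IMC2": imc2,
        "InverseDifferenceNormalized": float(np.sum(p / (1.0 + absdiff / Ng))),
        "InverseDifferenceMomentNormalized": float(np.sum(p / (1.0 + (iv - jv) ** 2 / Ng**2))),
    }
    return {name: out[name] for name in GLCM_SCALAR_NAMES}


def rotation_invariant_aggregate(per_direction: Sequence[float]) -> Tuple[float, float, float]:
    """(mean, range, angular variance) of one scalar across directions.

    Missing (NaN) directions are excluded; if every direction is missing all
    three aggregates are missing.  Angular variance is the population
    variance (ddof=0).
    """
    v = np.asarray(per_direction, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (math.nan, math.nan, math.nan)
    return (
        float(np.mean(v)),
        float(np.max(v) - np.min(v)),
        float(np.var(v)),
    )
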