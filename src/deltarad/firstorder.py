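"""First-order (histogram) features of raw in-ROI intensities.

Conventions (recorded in :data:`CONVENTIONS`): percentiles use linear
interpolation between order statistics; standard deviation is the sample
(n-1) estimator; skewness is the adjusted Fisher-Pearson coefficient;
kurtosis is the Pearson (normal = 3) definition, bias-corrected.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
from scipy import stats

FO_NAMES = (
    "Minimum",
    "Maximum",
    "Mean",
    "Standard.Deviation",
    "Percentile.1",
    "Percentile.5",
    "Percentile.95",
    "Percentile.99",
    "Skewness",
    "Kurtosis",
)

CONVENTIONS = {
    "percentile": "linear interpolation",
    "sd": "sample (ddof=1)",
    "skewness": "adjusted Fisher-Pearson (bias corrected)",
    "kurtosis": "Pearson, normal=3 (bias corrected)",
}


def first_order_features(intensities: np.ndarray) -> Dict[str, float]:
    """The 10 first-order statistics of a 1D array of in-ROI intensities.

    Empty input yields all-NaN; a singleton yields NaN for SD, skewness and
    kurtosis (undefined at n < 2).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        return {name: math.nan for name in FO_NAMES}
    out: Dict[str, float] = {
        "Minimum": float(np.min(x)),
        "Maximum": float(np.max(x)),
        "Mean": float(np.mean(x)),
        "Percentile.1": float(np.percentile(x, 1)),
        "Percentile.5": float(np.percentile(x, 5)),
        "Percentile.95": float(np.percentile(x, 95)),
        "Percentile.99": float(np.percentile(x, 99)),
    }
    if x.size < 2:
        out["Standard.Deviation"] = math.nan
        out["Skewness"] = math.nan
        out["Kurtosis"] = math.nan
    else:
        out["Standard.Deviation"] = float(np.std(x, ddof=1))
        if np.all(x == x[0]):
            # zero variance: moments beyond the mean are undefined
            out["Skewness"] = math.nan
            out["Kurtosis"] = math.nan
        else:
            out["Skewness"] = float(stats.skew(x, bias=False))
            out["Kurtosis"] = float(stats.kurtosis(x, fisher=False, bias=False))
    return {name: out[name] for name in FO_NAMES}
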