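"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain Python loops and the
defining sums, sharing no code with the package implementation.
"""

import math

import numpy as np


def brute_distance_from_mask(mask, spacing):
    """All-pairs minimum centre-to-centre Euclidean distance (mm)."""
    mask = np.asarray(mask, dtype=bool)
    targets = np.argwhere(mask)
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        best = math.inf
        for t in targets:
            d = math.sqrt(
                sum(((idx[k] - t[k]) * spacing[k]) ** 2 for k in range(3))
            )
            best = min(best, d)
        out[idx] = best
    return out


def brute_glcm(levels, mask, offset, n_levels):
    """Symmetric pair-enumeration co-occurrence matrix, normalized."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    counts = {}
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(idx[k] + offset[k] for k in range(3))
        if any(nb[k] < 0 or nb[k] >= shape[k] for k in range(3)):
            continue
        if not mask[nb]:
            continue
        a, b = int(levels[idx]), int(levels[nb])
        counts[(a, b)] = counts.get((a, b), 0) + 1
        counts[(b, a)] = counts.get((b, a), 0) + 1
    P = np.zeros((n_levels, n_levels))
    total = sum(counts.values())
    for (a, b), c in counts.items():
        P[a - 1, b - 1] = c / total if total else 0.0
    return P, total


def brute_glcm_scalars(P):
    """The 20 scalar summaries by explicit loops over the defining sums.

    Entropies in bits; IMC2 uses the nat-based exponential form (equivalent
    to the bit form up to the explicit ln 2 conversion).
    """
    Ng = P.shape[0]
    px = [sum(P[i][j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(P[i][j] for i in range(Ng)) for j in range(Ng)]
    mu_x = sum((i + 1) * px[i] for i in range(Ng))
    mu_y = sum((j + 1) * py[j] for j in range(Ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(Ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(Ng)))

    def H(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    p_sum = [0.0] * (2 * Ng + 1)  # index by i+j (levels 1-based), 2..2Ng
    p_diff = [0.0] * Ng  # index by |i-j|
    for i in range(Ng):
        for j in range(Ng):
            p_sum[i + j + 2] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    sum_avg = sum(k * p_sum[k] for k in range(2, 2 * Ng + 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2, 2 * Ng + 1))
    mu_d = sum(k * p_diff[k] for k in range(Ng))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(Ng))

    hxy = H(P.ravel())
    hx, hy = H(px), H(py)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(Ng)
        for j in range(Ng)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(Ng)
        for j in range(Ng)
        if px[i] * py[j] > 0
    )
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else math.nan
    # nat-based exponential form
    hxy_n, hxy2_n = hxy * math.log(2), hxy2 * math.log(2)
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2_n - hxy_n))))

    if sd_x > 0 and sd_y > 0:
        corr = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * P[i][j]
            for i in range(Ng)
            for j in range(Ng)
        ) / (sd_x * sd_y)
    else:
        corr = math.nan

    return {
        "Autocorrelation": sum(
            (i + 1) * (j + 1) * P[i][j] for i in range(Ng) for j in range(Ng)
        ),
        "Correlation": corr,
        "Contrast": sum((i - j) ** 2 * P[i][j] for i in range(Ng) for j in range(Ng)),
        "ClusterProminence": sum(
            (i + j + 2 - mu_x - mu_y) ** 4 * P[i][j]
            for i in range(Ng)
            for j in range(Ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - mu_x - mu_y) ** 3 * P[i][j]
            for i in range(Ng)
            for j in range(Ng)
        ),
        "Dissimilarity": sum(
            abs(i - j) * P[i][j] for i in range(Ng) for j in range(Ng)
        ),
        "Energy": sum(P[i][j] ** 2 for i in range(Ng) for j in range(Ng)),
        "Entropy": hxy,
        "Homogeneity": sum(
            P[i][j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng)
        ),
        "MaximumProbability": max(P[i][j] for i in range(Ng) for j in range(Ng)),
        "SumOfSquaresVariance": sum(
            (i + 1 - mu_x) ** 2 * P[i][j] for i in range(Ng) for j in range(Ng)
        ),
        "SumAverage": sum_avg,
        "SumVariance": sum_var,
        "SumEntropy": H(p_sum),
        "DifferenceVariance": diff_var,
        "DifferenceEntropy": H(p_diff),
        "IMC1": imc1,
        "IMC2": imc2,
        "InverseDifferenceNormalized": sum(
            P[i][j] / (1 + abs(i - j) / Ng) for i in range(Ng) for j in range(Ng)
        ),
        "InverseDifferenceMomentNormalized": sum(
            P[i][j] / (1 + (i - j) ** 2 / Ng**2) for i in range(Ng) for j in range(Ng)
        ),
    }


def brute_auc_pairs(scores, labels):
    """AUC by exhaustive positive-negative pair counting."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_signed_rank_p(x, y):
    """Two-sided exact signed-rank p by enumeration of all sign assignments.

    Requires tie-free nonzero absolute differences.
    """
    d = [a - b for a, b in zip(x, y) if a != b]
    n = len(d)
    absd = sorted(abs(v) for v in d)
    assert len(set(absd)) == n, "oracle requires tie-free differences"
    ranks = {v: i + 1 for i, v in enumerate(absd)}
    w_obs = sum(ranks[abs(v)] for v in d if v > 0)
    dist = []
    for bits in range(2**n):
        w = sum(ranks[abs(d[k])] for k in range(n) if (bits >> k) & 1)
        dist.append(w)
    n_total = len(dist)
    p_le = sum(1 for w in dist if w <= w_obs) / n_total
    p_ge = sum(1 for w in dist if w >= w_obs) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_first_order(values):
    """The 10 first-order statistics from the sorted sample, by formula."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mean = sum(xs) / n

    def percentile(q):
        # linear interpolation between order statistics
        h = (n - 1) * q / 100.0
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in xs) / (n - 1))
    g1 = m3 / m2**1.5
    skew_adj = math.sqrt(n * (n - 1)) / (n - 2) * g1
    g2 = m4 / m2**2 - 3.0
    kurt_unbiased_fisher = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    return {
        "Minimum": xs[0],
        "Maximum": xs[-1],
        "Mean": mean,
        "Standard.Deviation": sd,
        "Percentile.1": percentile(1),
        "Percentile.5": percentile(5),
        "Percentile.95": percentile(95),
        "Percentile.99": percentile(99),
        "Skewness": skew_adj,
        "Kurtosis": kurt_unbiased_fisher + 3.0,
    }
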