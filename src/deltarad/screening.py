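"""Train/test split, per-feature AUC + DeLong CI, rank-sum tests, and the
dual-cohort feature selection rule.

The AUC is the Mann-Whitney probability (#concordant pairs + half the ties)
/ (n1*n0), identical to the trapezoidal area under the empirical ROC.
Reported per-feature AUCs are oriented so AUC >= 0.5; the orientation sign
is kept alongside.  No multiple-testing correction is applied at this
stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import PCR
from .deltas import feature_columns

POSITIVE_LABEL = PCR


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint train/test subject-ID partition."""

    train_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def stratified_split(
    labels: pd.Series,
    ratio: Tuple[int, int] = (2, 1),
    seed: int = 0,
) -> CohortSplit:
    """Response-stratified split; per class, round(train_frac * n) half-up
    subjects go to training and the rest to testing.

    With a 78/85 cohort at 2:1 this yields 52/57 training and 26/28 testing.
    """
    labels = pd.Series(labels)
    train_frac = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train: List[str] = []
    test: List[str] = []
    for cls in sorted(labels.unique()):
        ids = np.asarray(labels.index[labels == cls], dtype=object)
        if ids.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 subjects")
        n_train = int(math.floor(train_frac * ids.size + 0.5))  # round half up
        perm = rng.permutation(ids.size)
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return CohortSplit(tuple(sorted(train)), tuple(sorted(test)), seed)


def _drop_missing(scores: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    keep = np.isfinite(scores)
    return scores[keep], y[keep]


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Raw (unoriented) Mann-Whitney AUC of ``scores`` for the positive class."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    s, y = _drop_missing(s, y)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auc: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def oriented_auc(scores: Sequence[float], labels: Sequence[bool]) -> Tuple[float, int]:
    """(AUC oriented >= 0.5, orientation sign in {+1, -1})."""
    a = auc(scores, labels)
    return (a, 1) if a >= 0.5 else (1.0 - a, -1)


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """DeLong point estimate and variance of the AUC (midrank formulation)."""
    x = scores[y]   # positives
    z = scores[~y]  # negatives
    m, n = x.size, z.size
    all_s = np.concatenate([x, z])
    tx = stats.rankdata(x)
    tz = stats.rankdata(z)
    t_all = stats.rankdata(all_s)
    v10 = (t_all[:m] - tx) / n           # placement of positives among negatives
    v01 = 1.0 - (t_all[m:] - tz) / m     # placement of negatives among positives
    a = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def auc_ci95(scores: Sequence[float], labels: Sequence[bool]) -> Tuple[float, float]:
    """DeLong 95% CI for the (raw) AUC, truncated to [0, 1].

    Degenerate variance (e.g. perfect separation) collapses the interval to
    the point estimate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    s, y = _drop_missing(s, y)
    if y.all() or not y.any():
        raise ValueError("auc_ci95: both classes must be present")
    a, var = _delong_variance(s, y)
    if var <= 0:
        return (a, a)
    half = 1.959963984540054 * math.sqrt(var)
    return (max(0.0, a - half), min(1.0, a + half))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value: exact when n1*n0 <= 400 and the
    pooled sample is tie-free, otherwise tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test: both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def univariate_screen(
    table: pd.DataFrame,
    split: CohortSplit,
    threshold: float = 0.70,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature train/test AUC + CI + rank-sum p and the selection flag.

    A feature is selected iff train AUC >= threshold AND test AUC >=
    threshold AND the training rank-sum p < alpha.  AUCs are oriented using
    the training direction for both cohorts.
    """
    train = table.loc[list(split.train_ids)]
    test = table.loc[list(split.test_ids)]
    y_train = (train["response"] == POSITIVE_LABEL).to_numpy()
    y_test = (test["response"] == POSITIVE_LABEL).to_numpy()

    records = []
    for col in feature_columns(table):
        s_train = train[col].to_numpy(dtype=float)
        s_test = test[col].to_numpy(dtype=float)
        st, yt = _drop_missing(s_train, y_train)
        ss, ys = _drop_missing(s_test, y_test)
        if yt.sum() in (0, len(yt)) or ys.sum() in (0, len(ys)) or len(yt) < 4 or len(ys) < 2:
            records.append(
                dict(feature=col, auc_train=math.nan, ci_lo_train=math.nan,
                     ci_hi_train=math.nan, auc_test=math.nan, ci_lo_test=math.nan,
                     ci_hi_test=math.nan, p_ranksum_train=math.nan, orientation=0,
                     selected=False)
            )
            continue
        a_train_raw = auc(st, yt)
        sign = 1 if a_train_raw >= 0.5 else -1
        a_train = a_train_raw if sign == 1 else 1.0 - a_train_raw
        a_test_raw = auc(ss, ys)
        a_test = a_test_raw if sign == 1 else 1.0 - a_test_raw
        lo_t, hi_t = auc_ci95(sign * st, yt)
        lo_s, hi_s = auc_ci95(sign * ss, ys)
        p = rank_sum_test(st[yt], st[~yt])
        records.append(
            dict(
                feature=col,
                auc_train=a_train, ci_lo_train=lo_t, ci_hi_train=hi_t,
                auc_test=a_test, ci_lo_test=lo_s, ci_hi_test=hi_s,
                p_ranksum_train=p, orientation=sign,
                selected=bool(a_train >= threshold and a_test >= threshold and p < alpha),
            )
        )
    return pd.DataFrame.from_records(records).set_index("feature")


def screen(results: pd.DataFrame, threshold: float = 0.70, alpha: float = 0.05) -> List[str]:
    """Names of features passing the dual-cohort rule on a results table."""
    ok = (
        (results["auc_train"] >= threshold)
        & (results["auc_test"] >= threshold)
        & (results["p_ranksum_train"] < alpha)
    )
    return list(results.index[ok.fillna(False)])
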