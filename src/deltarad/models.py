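"""Elastic-net logistic regression model suite over declared feature blocks.

Model names encode (regions, blocks, feature class), e.g.
``Peritumoral_Tumoral_DCE_BL_C4_AD-C4BL_RD-C4BL_FO``.  Designs are
standardized with training-set statistics only.  Both elastic-net
hyperparameters (the L1/L2 mixing ratio and the penalty strength) are tuned
on a grid by mean 5-fold stratified cross-validated AUC, ties broken toward
the strongest penalty; the model is then refit on the full training set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import REGIONS
from .deltas import BLOCKS
from .features import feature_local_names, full_feature_name
from .screening import POSITIVE_LABEL, CohortSplit, auc, auc_ci95

L1_RATIO_GRID: Tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))
C_GRID: Tuple[float, ...] = tuple(float(c) for c in np.logspace(-2, 2, 9))

#: The 13 block-combination models reported with dual AUC >= 0.75.
SUITE_TOP: Tuple[str, ...] = (
    "Peritumoral_DCE_AD-C4BL_FO",
    "Peritumoral_DCE_RD-C4BL_FO",
    "Peritumoral_DCE_BL_C2_C4_FO",
    "Peritumoral_DCE_BL_C2_C4_AD-C2BL_RD-C2BL_AD-C4BL_RD-C4BL_AD-C4C2_RD-C4C2_FO",
    "Tumoral_DCE_AD-C4BL_FO",
    "Tumoral_DCE_RD-C4BL_FO",
    "Tumoral_DCE_BL_C4_AD-C4BL_RD-C4BL_FO",
    "Peritumoral_Tumoral_DCE_AD-C4BL_FO",
    "Peritumoral_Tumoral_DCE_RD-C4BL_FO",
    "Peritumoral_Tumoral_DCE_BL_C4_AD-C4BL_RD-C4BL_FO",
    "Peritumoral_Tumoral_DCE_C2_C4_AD-C4C2_RD-C4C2_FO",
    "Peritumoral_Tumoral_DCE_BL_C2_C4_FO",
    "Peritumoral_Tumoral_DCE_BL_C2_C4_AD-C2BL_RD-C2BL_AD-C4BL_RD-C4BL_AD-C4C2_RD-C4C2_FO",
)

#: The 7 additional single/dual time-point models reported with dual AUC > 0.70.
SUITE_TIMEPOINT: Tuple[str, ...] = (
    "Peritumoral_DCE_C4_FO",
    "Peritumoral_DCE_BL_C4_FO",
    "Peritumoral_DCE_C2_C4_FO",
    "Tumoral_DCE_C2_FO",
    "Tumoral_DCE_C4_FO",
    "Tumoral_DCE_BL_C2_FO",
    "Tumoral_DCE_BL_C4_FO",
)

DEFAULT_SUITE: Tuple[str, ...] = SUITE_TOP + SUITE_TIMEPOINT


@dataclass(frozen=True)
class ModelSpec:
    """Declarative definition of one feature-block model."""

    regions: Tuple[str, ...]
    blocks: Tuple[str, ...]
    feature_class: str  # "FO", "GLCM" or "both"

    def __post_init__(self) -> None:
        if not self.regions or any(r not in REGIONS for r in self.regions):
            raise ValueError(f"regions must be a nonempty subset of {REGIONS}")
        if not self.blocks or any(b not in BLOCKS for b in self.blocks):
            raise ValueError(f"blocks must be a nonempty subset of {BLOCKS}")
        if self.feature_class not in ("FO", "GLCM", "both"):
            raise ValueError(f"feature_class must be FO, GLCM or both")

    @property
    def name(self) -> str:
        cls = {"FO": "FO", "GLCM": "GLCM", "both": "FO_GLCM"}[self.feature_class]
        return "_".join([*self.regions, "DCE", *self.blocks, cls])

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        """Parse ``<Regions>_DCE_<Blocks>_<Class>`` (whitespace tolerated)."""
        tokens = [t for t in name.replace(" ", "").split("_") if t]
        if "DCE" not in tokens:
            raise ValueError(f"cannot parse model name {name!r}: no DCE token")
        i = tokens.index("DCE")
        regions = tuple(tokens[:i])
        rest = tokens[i + 1:]
        if rest[-2:] == ["FO", "GLCM"]:
            feature_class, blocks = "both", tuple(rest[:-2])
        elif rest[-1] in ("FO", "GLCM"):
            feature_class, blocks = rest[-1], tuple(rest[:-1])
        else:
            raise ValueError(f"cannot parse model name {name!r}: no class suffix")
        return cls(regions=regions, blocks=blocks, feature_class=feature_class)

    def columns(self) -> List[str]:
        """Resolve the full feature-column list this model uses."""
        local = feature_local_names()
        if self.feature_class == "FO":
            local = [n for n in local if n.startswith("FO_")]
        elif self.feature_class == "GLCM":
            local = [n for n in local if n.startswith("GLCM_")]
        return [
            full_feature_name(region, block, n)
            for region in self.regions
            for block in self.blocks
            for n in local
        ]


@dataclass
class FitResult:
    """A fitted elastic-net model plus its tuning trace."""

    spec: ModelSpec
    coefficients: Dict[str, float]
    intercept: float
    l1_ratio: float
    C: float
    cv_mean_auc: float
    columns: Tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    auc_train: float = math.nan
    ci_train: Tuple[float, float] = (math.nan, math.nan)
    auc_test: float = math.nan
    ci_test: Tuple[float, float] = (math.nan, math.nan)
    notes: List[str] = field(default_factory=list)


def build_design(
    spec: ModelSpec,
    table: pd.DataFrame,
    split: CohortSplit,
) -> Tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """(X_train, y_train, X_test, y_test, mean, sd) for one model.

    Columns are restricted to the spec and standardized with training-set
    statistics; zero-training-variance columns are dropped with a warning;
    subjects with any missing value in the design are dropped per cohort.
    """
    cols = spec.columns()
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"model {spec.name}: missing columns {missing_cols[:3]} ...")
    if not cols:
        raise ValueError(f"model {spec.name}: empty column set")

    train = table.loc[list(split.train_ids), cols + ["response"]].copy()
    test = table.loc[list(split.test_ids), cols + ["response"]].copy()
    train = train.dropna(axis=0)
    test = test.dropna(axis=0)
    if len(train) < 10:
        raise ValueError(f"model {spec.name}: fewer than 10 complete training subjects")

    X_train = train[cols]
    sd = X_train.std(axis=0, ddof=1).to_numpy()
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(
            f"model {spec.name}: dropping {len(dropped)} zero-variance columns", stacklevel=2
        )
        cols = [c for c, k in zip(cols, keep) if k]
        X_train = X_train[cols]
        sd = sd[keep]
    if not cols:
        raise ValueError(f"model {spec.name}: all columns have zero training variance")
    mean = X_train.mean(axis=0).to_numpy()

    Xt = (X_train - mean) / sd
    Xs = (test[cols] - mean) / sd
    y_train = (train["response"] == POSITIVE_LABEL).to_numpy()
    y_test = (test["response"] == POSITIVE_LABEL).to_numpy()
    return Xt, y_train, Xs, y_test, mean, sd


def _fit_one(X: np.ndarray, y: np.ndarray, l1_ratio: float, C: float) -> LogisticRegression:
    model = LogisticRegression(
        solver="saga",
        l1_ratio=l1_ratio,
        C=C,
        max_iter=3000,
        tol=1e-5,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def fit_elastic_net_cv(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    l1_ratios: Sequence[float] = L1_RATIO_GRID,
    c_grid: Sequence[float] = C_GRID,
    spec: Optional[ModelSpec] = None,
) -> FitResult:
    """Tune (l1_ratio, C) by mean stratified-CV AUC, refit on all of X_train."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=bool)
    cols = tuple(X_train.columns) if hasattr(X_train, "columns") else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    for _, val_idx in folds:
        if y[val_idx].all() or not y[val_idx].any():
            raise ValueError("a CV fold lost one of the classes; cohort too small")

    best: Optional[Tuple[float, float, float]] = None  # (cv_auc, C, l1_ratio)
    notes: List[str] = []
    for l1_ratio in l1_ratios:
        for C in c_grid:
            fold_aucs = []
            try:
                for tr_idx, val_idx in folds:
                    m = _fit_one(X[tr_idx], y[tr_idx], l1_ratio, C)
                    scores = m.decision_function(X[val_idx])
                    fold_aucs.append(auc(scores, y[val_idx]))
            except Exception as exc:  # pragma: no cover - solver failure path
                notes.append(f"grid point (l1_ratio={l1_ratio}, C={C}) skipped: {exc}")
                warnings.warn(notes[-1], stacklevel=2)
                continue
            mean_auc = float(np.mean(fold_aucs))
            # ties broken toward the strongest penalty (smallest C), then sparser mix
            if (
                best is None
                or mean_auc > best[0] + 1e-12
                or (abs(mean_auc - best[0]) <= 1e-12
                    and (C < best[1] or (C == best[1] and l1_ratio > best[2])))
            ):
                best = (mean_auc, C, l1_ratio)
    if best is None:
        raise RuntimeError("elastic-net tuning failed at every grid point")

    cv_auc, C_best, l1_best = best
    final = _fit_one(X, y, l1_best, C_best)
    coef = final.coef_.ravel()
    coefficients = {c: float(w) for c, w in zip(cols, coef) if w != 0.0}
    a_train = auc(final.decision_function(X), y)
    ci_train = auc_ci95(final.decision_function(X), y)
    return FitResult(
        spec=spec if spec is not None else ModelSpec(("Tumoral",), ("BL",), "FO"),
        coefficients=coefficients,
        intercept=float(final.intercept_[0]),
        l1_ratio=l1_best,
        C=C_best,
        cv_mean_auc=cv_auc,
        columns=cols,
        scaler_mean=np.zeros(len(cols)),
        scaler_sd=np.ones(len(cols)),
        auc_train=a_train,
        ci_train=ci_train,
        notes=notes,
    )


def linear_predictor(fit: FitResult, X: pd.DataFrame) -> np.ndarray:
    """Score standardized designs with the sparse fitted coefficients."""
    scores = np.full(len(X), fit.intercept, dtype=float)
    for c, w in fit.coefficients.items():
        scores += w * np.asarray(X[c], dtype=float)
    return scores


def evaluate_model(
    fit: FitResult, X_test: pd.DataFrame, y_test: np.ndarray
) -> Tuple[float, Tuple[float, float]]:
    """Test AUC with DeLong 95% CI for a fitted model."""
    scores = linear_predictor(fit, X_test)
    if len(fit.coefficients) == 0:
        # fully shrunk model: constant scores, AUC is 0.5 by the tie convention
        scores = np.zeros(len(X_test))
    a = auc(scores, y_test)
    try:
        ci = auc_ci95(scores, y_test)
    except ValueError:
        ci = (math.nan, math.nan)
    return a, ci


def run_model_suite(
    specs: Sequence[ModelSpec],
    table: pd.DataFrame,
    split: CohortSplit,
    seed: int = 0,
    threshold: float = 0.75,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit and evaluate every spec; flag rows meeting the dual-AUC rule.

    Per-spec failures are recorded in the ``error`` column and the suite
    continues.
    """
    records = []
    for spec in specs:
        row = dict(
            model=spec.name, auc_train=math.nan, ci_lo_train=math.nan,
            ci_hi_train=math.nan, auc_test=math.nan, ci_lo_test=math.nan,
            ci_hi_test=math.nan, cv_mean_auc=math.nan, l1_ratio=math.nan,
            C=math.nan, n_nonzero=0, flagged=False, error="",
        )
        try:
            Xt, yt, Xs, ys, _, _ = build_design(spec, table, split)
            fit = fit_elastic_net_cv(Xt, yt, seed=seed, spec=spec, **fit_kwargs)
            a_test, ci_test = evaluate_model(fit, Xs, ys)
            row.update(
                auc_train=fit.auc_train, ci_lo_train=fit.ci_train[0],
                ci_hi_train=fit.ci_train[1], auc_test=a_test,
                ci_lo_test=ci_test[0], ci_hi_test=ci_test[1],
                cv_mean_auc=fit.cv_mean_auc, l1_ratio=fit.l1_ratio, C=fit.C,
                n_nonzero=len(fit.coefficients),
                flagged=bool(fit.auc_train >= threshold and a_test >= threshold),
            )
        except Exception as exc:
            row["error"] = str(exc)
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("model")


def default_suite() -> List[ModelSpec]:
    """The 20 published model definitions, parsed from their names."""
    return [ModelSpec.from_name(n) for n in DEFAULT_SUITE]
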