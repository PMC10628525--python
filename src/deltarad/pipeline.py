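"""End-to-end pipeline: cohort -> ROIs -> features -> deltas -> screening ->
model suite -> reliability, with deterministic, auditable outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from . import io as drio
from .core import REGIONS, TIMEPOINTS, RoiMask, SubjectRecord
from .deltas import assemble_longitudinal_table
from .features import CONVENTIONS_FINGERPRINT, FeatureVector, extract_features
from .geometry import PeritumoralSpec, peritumoral_ring
from .glcm import GRAY_LEVELS
from .models import ModelSpec, default_suite, run_model_suite
from .reliability import reliability_table, summarize_reliability
from .screening import stratified_split, univariate_screen
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run (simulate-mode or manifest-mode)."""

    manifest: Optional[str] = None
    simulate: Optional[CohortConfig] = None
    thickness_mm: float = 10.0
    gray_levels: Sequence[int] = GRAY_LEVELS
    split_ratio: tuple = (2, 1)
    seed: int = 0
    univariate_threshold: float = 0.70
    multivariate_threshold: float = 0.75
    suite: Union[str, List[str]] = "default"
    out_dir: str = "deltarad_run"
    run_reliability: bool = True
    fit_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for thr in (self.univariate_threshold, self.multivariate_threshold):
            if not (0.5 < thr < 1):
                raise ValueError(f"thresholds must lie in (0.5, 1), got {thr}")
        if any(g < 2 for g in self.gray_levels):
            raise ValueError("gray levels must each be >= 2")
        if self.manifest is None and self.simulate is None:
            raise ValueError("config needs either a manifest path or a simulate block")


def extract_subject_features(
    record: SubjectRecord,
    thickness_mm: float = 10.0,
    gray_levels: Sequence[int] = GRAY_LEVELS,
    mask_override: Optional[Mapping[str, RoiMask]] = None,
) -> Dict[str, Dict[str, FeatureVector]]:
    """All (region x time point) feature vectors for one subject.

    ``mask_override`` substitutes per-time-point tumor masks (used for
    second-reader and repeat extractions).
    """
    spec = PeritumoralSpec(thickness_mm)
    out: Dict[str, Dict[str, FeatureVector]] = {r: {} for r in REGIONS}
    for tp in TIMEPOINTS:
        td = record.timepoints[tp]
        tumor = mask_override[tp] if mask_override is not None else td.effective_mask()
        ring = peritumoral_ring(tumor, td.volume.spacing, spec)
        out["Tumoral"][tp] = extract_features(td.volume, tumor, "Tumoral", tp, gray_levels)
        out["Peritumoral"][tp] = extract_features(
            td.volume, ring, "Peritumoral", tp, gray_levels
        )
    return out


def build_feature_table(
    cohort: Sequence[SubjectRecord],
    thickness_mm: float = 10.0,
    gray_levels: Sequence[int] = GRAY_LEVELS,
    reader: str = "reader1",
) -> pd.DataFrame:
    """Longitudinal feature table for the whole cohort, for one reader.

    ``reader`` is one of ``reader1``, ``reader2``, ``reader1_repeat``.
    """
    features = {}
    for rec in cohort:
        override = None
        if reader == "reader2":
            override = rec.reader2_masks
        elif reader == "reader1_repeat":
            override = rec.reader1_repeat_masks
        if reader != "reader1" and override is None:
            raise ValueError(f"subject {rec.subject_id}: no {reader} masks available")
        features[rec.subject_id] = extract_subject_features(
            rec, thickness_mm, gray_levels, mask_override=override
        )
    return assemble_longitudinal_table(cohort, features)


def _config_fingerprint(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        logger.info("simulating cohort: %d + %d subjects",
                    config.simulate.n_pcr, config.simulate.n_nonpcr)
        cohort = generate_cohort(config.simulate)
    else:
        logger.info("loading cohort manifest %s", config.manifest)
        cohort = drio.load_cohort(config.manifest)

    logger.info("extracting features for %d subjects", len(cohort))
    table = build_feature_table(cohort, config.thickness_mm, config.gray_levels)
    table.to_csv(out / "features.csv")

    labels = table["response"]
    split = stratified_split(labels, config.split_ratio, config.seed)
    (out / "split.json").write_text(
        json.dumps(
            {"train_ids": list(split.train_ids), "test_ids": list(split.test_ids),
             "seed": split.seed},
            indent=2,
        )
    )

    logger.info("univariate screening (%d features)", table.shape[1] - 1)
    screen_df = univariate_screen(table, split, config.univariate_threshold)
    screen_df.to_csv(out / "screen.csv")

    if config.suite == "default":
        specs = default_suite()
    else:
        specs = [ModelSpec.from_name(n) for n in config.suite]
    logger.info("fitting %d multivariate models", len(specs))
    suite_df = run_model_suite(
        specs, table, split, seed=config.seed,
        threshold=config.multivariate_threshold, **config.fit_kwargs,
    )
    suite_df.to_csv(out / "suite.csv")

    if config.run_reliability and all(r.reader2_masks is not None for r in cohort):
        logger.info("interreader reliability analysis")
        table_r2 = build_feature_table(
            cohort, config.thickness_mm, config.gray_levels, reader="reader2"
        )
        table_rep = None
        if all(r.reader1_repeat_masks is not None for r in cohort):
            table_rep = build_feature_table(
                cohort, config.thickness_mm, config.gray_levels, reader="reader1_repeat"
            )
        rel = reliability_table(table, table_r2, table_rep)
        rel.to_csv(out / "reliability.csv")
        (out / "reliability_summary.json").write_text(
            json.dumps(summarize_reliability(rel), indent=2)
        )

    manifest = {
        "config_fingerprint": _config_fingerprint(config),
        "conventions": CONVENTIONS_FINGERPRINT,
        "n_subjects": len(cohort),
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "seed": config.seed,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
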