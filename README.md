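# deltarad

Longitudinal delta-radiomics of dynamic contrast-enhanced (DCE) MRI for
early prediction of treatment response. The package implements a complete,
reproducible analysis pipeline:

- **Synthetic cohort generator** — ellipsoidal enhancing tumors that shrink
  and de-enhance over three imaging time points (BL, C2, C4), with
  configurable class-specific decline, spatial texture, noise, and simulated
  second-reader / repeat segmentations (`deltarad.synthetic`).
- **ROI geometry** — peritumoral shell of fixed physical thickness (default
  10 mm) via a spacing-aware Euclidean distance transform
  (`deltarad.geometry`).
- **Feature extraction** — 310 features per ROI per time point: 10
  first-order histogram statistics plus 300 rotation-invariant GLCM texture
  features (20 scalars × {mean, range, angular variance} × 5 gray-level
  settings 8/16/32/64/256, aggregated over the 13 canonical 3D directions)
  (`deltarad.firstorder`, `deltarad.glcm`, `deltarad.features`).
- **Longitudinal deltas** — absolute and relative differences between time
  point pairs (C2BL, C4BL, C4C2), assembled into a wide cohort table with
  `Region_DCE_Block_Class_Name` column naming (`deltarad.deltas`).
- **Univariate screening** — response-stratified 2:1 train/test split,
  per-feature Mann–Whitney AUC with DeLong 95% CIs, Wilcoxon rank-sum
  tests, and the dual-cohort selection rule (AUC ≥ 0.70 in both cohorts,
  p < 0.05) (`deltarad.screening`).
- **Multivariate models** — elastic-net logistic regression over declared
  feature blocks, tuned by mean 5-fold stratified CV AUC over a grid of
  (mixing ratio, penalty strength), evaluated on the held-out test set
  (`deltarad.models`).
- **Interreader reliability** — per-feature Pearson correlation, Wilcoxon
  signed-rank tests, and an interreader-to-intrareader variance ratio
  (`deltarad.reliability`).

## Test

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracle comparisons (GLCM pair enumeration,
all-pairs distance transforms, exhaustive AUC pair counting, sign-flip
enumeration for the signed-rank test), property tests, and an acceptance
suite (`tests/test_acceptance.py`) covering structural targets and
parameter-recovery / null-calibration experiments on synthetic cohorts.
The full run takes roughly 10–15 minutes on one CPU; most of it is the
synthetic-cohort recovery experiments.

## CLI

All stages are exposed under a single entry point:

```bash
deltarad simulate --config cohort.json --out cohort_dir --seed 1
deltarad ring --tumor cohort_dir/S0000/BL_tumor_mask.nii.gz --thickness 10 --out ring.nii.gz
deltarad extract --volume v.nii.gz --mask m.nii.gz --region tumoral --timepoint C4 --out features.csv
deltarad deltas --manifest cohort_dir/manifest.csv --out table.csv
deltarad screen --features table.csv --seed 1 --threshold 0.70 --out screen.csv
deltarad fit --features table.csv --suite default --seed 1 --out suite.csv
deltarad reliability --r1 a.csv --r2 b.csv --r1rep a2.csv --out reliability.csv
deltarad run --config pipeline.json --out run_dir --seed 1
```

`deltarad run` executes the full pipeline (simulate/ingest → peritumoral
rings → extraction → deltas → split → univariate screen → model suite →
reliability) and writes stage CSVs plus a run manifest; reruns with the same
config are byte-identical.

Example pipeline config:

```json
{
  "simulate": {"n_pcr": 20, "n_nonpcr": 20, "image_shape": [32, 32, 32]},
  "suite": ["Tumoral_DCE_RD-C4BL_FO", "Peritumoral_DCE_C4_FO"],
  "thickness_mm": 10.0
}
```

## Conventions

Choices that the underlying methodology leaves open are pinned and recorded
in the extraction metadata fingerprint: equal-width min–max quantization
per ROI; symmetric GLCMs at offset distance 1 voxel over 13 directions;
base-2 entropies with 0·log 0 = 0; sample (n−1) SD, adjusted
Fisher–Pearson skewness, Pearson kurtosis; linear-interpolation
percentiles; RD = (late − early)/|early| as a fraction; population variance
for the angular aggregate; AUCs oriented ≥ 0.5 with the orientation sign
stored; no multiple-testing correction at the screening stage.
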