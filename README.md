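# lipomics

A tested, reusable pipeline for one of the classic problems of
musculoskeletal imaging: telling apart benign **lipomas** from
**atypical lipomatous tumours (ALTs)** — low-grade liposarcomas whose
MRI appearance overlaps with lipoma — without a biopsy.  The package
implements the radiomics-versus-deep-learning comparison workflow for
this task and ships a synthetic phantom cohort generator so that every
stage is runnable and testable without any patient data.

## What it does

Given 3D MR volumes with binary lesion masks (NIfTI) and a per-case
metadata table (`case_id,batch,label`), the pipeline

1. **resamples** each volume to an isotropic grid;
2. **extracts 92 radiomic features** per lesion: shape (14), histogram
   (14, 256-bin), and texture from four matrix families built on
   equal-probability quantized volumes at Ng ∈ {8, 16, 24, 32, 40, 48,
   64} — GLCM (21, four in-plane directions at offset 1), GLRLM (13),
   GLSZM (13, 26-connected 3D zones), NGTDM (5, 26-neighbourhood) —
   plus a Gabor filter bank (12: 5 scales from minimal wavelength 3, 6
   orientations).  Matrix features are averaged over directions and
   then over Ng; formulae follow the IBSI reference definitions;
3. **harmonizes** the feature table with parametric empirical-Bayes
   **ComBat**, removing per-batch location/scale effects
   `x = α + γ_batch + δ_batch·ε` (batch = acquisition protocol, e.g.
   fat-suppression technique), with optional protection of the class
   label during estimation;
4. **benchmarks four classifiers** (logistic regression, RBF SVM,
   random forest, gradient boosting) on raw vs. harmonized features
   with patient-grouped stratified k-fold CV, reporting AUC /
   sensitivity / specificity per fold, **DeLong** tests for correlated
   AUCs, **McNemar/χ²** for paired predictions, and decision-threshold
   sweeps;
5. trains a small **from-scratch CNN** on 224×224 z-scored lesion
   crops (three conv–batchnorm–ReLU–maxpool–dropout blocks, dense 32,
   sigmoid) as the image-based baseline, grouped by patient.

The **phantom generator** produces two-class cohorts whose lesions
differ only in internal texture (nodular inclusions and septum-like
planes in the malignant class) and injects batch effects at the *image*
level (gain, offset, blur), so harmonization is exercised end-to-end
against an acquisition-style confounder with known ground truth.

## Worked example

```python
from lipomics import run_benchmark
from lipomics.evaluate import FAST_GRIDS
from lipomics.features import extract_cohort_in_memory
from lipomics.phantom import small_spec

table = extract_cohort_in_memory(small_spec(seed=11, n_cases=40))
report = run_benchmark(table, k=5, grids=FAST_GRIDS, seed=11)
for row in report["rows"]:
    print(row["dataset"], row["classifier"],
          f"{row['auc_mean']:.2f} ± {row['auc_sd']:.2f}")
```

prints (gradient-boosting rows shown; `examples/04_benchmark_classifiers.py`
prints the full grid):

```
radiomics        GB 0.86 ± 0.13
radiomics_combat GB 0.97 ± 0.07
```

Raw features are dragged down by the injected acquisition differences
(a 1.5× gain, offset and blur in one batch); after per-fold ComBat
harmonization the classifier recovers the lesion-texture signal, the
pooled out-of-fold AUC moving from 0.84 to 0.96 (DeLong p ≈ 0.049) on
this cohort.  The `examples/` directory holds one short script per
capability (simulation, extraction, harmonization, benchmarking, CNN).

A thin CLI mirrors the stages:

```bash
lipomics simulate --preset study --seed 7 --out cohort/
lipomics extract --manifest cohort/manifest.csv --out features.csv
lipomics harmonize --features features.csv --out corrected.csv
lipomics benchmark --features features.csv --k 10 --seed 7 --out report.json
lipomics run-all --out run/
```

## Layout

```
src/lipomics/
  phantom.py        synthetic multi-batch cohort generator (NIfTI + CSV)
  preprocessing.py  isotropic resampling, lesion crops, z-score
  quantize.py       equal-probability quantization; GLCM/GLRLM/GLSZM/NGTDM
  features.py       the 92-feature catalog and cohort extraction
  combat.py         parametric empirical-Bayes ComBat (fit/transform)
  evaluate.py       grouped CV, four classifiers, DeLong/McNemar, sweeps
  cnn.py            NumPy CNN (layers, Adam/SGD, augmentation, grouped CV)
  pipeline.py       run-all orchestration and provenance
  cli.py            thin argparse CLI
docs/methods.md     model assumptions, parameter choices, limitations
examples/           one narrative script per capability
```
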