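# Methods

This note documents the models, the parameter choices that matter, and
the limits of what the bundled phantom experiments can show.

## The problem and the two arms

Lipomas and atypical lipomatous tumours (ALTs, low-grade liposarcomas)
overlap on MRI; the discriminating signal radiologists describe is
*internal heterogeneity* — nodularity and thickened septa inside an
otherwise fatty lesion.  The package compares two ways of extracting
that signal from a segmented 3D lesion: a fixed 92-feature radiomic
description fed to classical classifiers, and a small CNN trained
directly on 2D lesion crops.  Because multi-centre MRI is acquired
under heterogeneous protocols, the radiomics arm includes ComBat
batch-effect harmonization; the central empirical question the
pipeline answers on its phantom cohorts is how much harmonization
buys.

## Radiomic features

**Resampling.** Volumes and masks are resampled to an isotropic grid
(default 1 mm) by nearest-neighbour interpolation; trilinear is
available via `interp="linear"`. No intensity normalization or
filtering is applied before feature extraction.

**Quantization.** Masked intensities are discretised into Ng levels
using equal-probability thresholds: threshold k is the smallest masked
intensity whose empirical CDF reaches k/Ng, and ties map to the lower
level. With all-distinct intensities the level occupancies differ by
at most one voxel (asserted in tests). Texture is computed at all
Ng ∈ {8, 16, 24, 32, 40, 48, 64}.

**Matrix families.** GLCM and GLRLM use the four classic in-plane
directions (0°, 45°, 90°, 135°) at offset 1, applied slice-wise with
counts pooled over axial slices; the GLCM counts both orderings and is
normalized to sum 1. GLSZM zones and NGTDM neighbourhoods are 3D with
26-connectivity. Voxels whose offset partner or neighbour falls
outside the mask contribute nothing. Each GLCM/GLRLM feature is the
unweighted mean over the four directions, and every matrix feature is
then the unweighted mean over the seven Ng values — the catalog keeps
one value per feature. Formulae follow the IBSI definitions, with
these degenerate-input conventions: correlation-type features with
zero marginal variance return 1; logs are base 2 with 0·log 0 ≡ 0;
NGTDM uses ε = 1e-12 and coarseness is capped at 1e6.

**Catalog.** 92 features: shape 14, histogram 14 (256 equal-width
bins for entropy/uniformity; excess kurtosis), GLCM 21, GLRLM 13,
GLSZM 13, NGTDM 5, Gabor 12. The non-matrix lists (shape, histogram,
Gabor) are this package's reconstruction of a conventional catalog of
those sizes and are frozen in `features.FEATURE_CATALOG`; group sizes
are asserted at import time. Shape uses a marching-cubes surface on a
mask smoothed with σ = 0.8 voxel (the raw voxel staircase otherwise
inflates the area of round lesions by ~8%), PCA axis lengths 4√λ, and
the exact boundary-pair maximum diameter (convex hull above 5 000
boundary voxels).

**Gabor bank.** Wavelengths follow a half-octave ladder from the
minimal wavelength 3 ({3, 3√2, 6, 6√2, 12} pixels) at orientations
kπ/6, k = 0..5. Kernels are made exactly DC-free (complex mean
subtracted) and slices are symmetric-padded before FFT convolution, so
a constant image yields zero response. Per filter the mean magnitude
over masked pixels is pooled across slices; the 12 features are the
per-orientation mean and SD across the five scales.

## ComBat harmonization

The parametric empirical-Bayes location/scale model: per feature f and
batch i, x = α_f + γ_if + δ_if·ε with ε ~ N(0, σ_f²). Features are
standardized by the grand mean (batch-size-weighted) and pooled scale,
per-batch raw estimates are shrunk toward normal (γ) and inverse-gamma
(δ²) priors by the standard fixed-point iteration (tolerance 1e-4, cap
100; convergence is monitored per batch). Per-batch variances use the
population divisor by default so that a single-batch fit is an exact
identity; `ddof=1` reproduces the Bioconductor reference estimator,
and one test cross-checks corrected values against `sva::ComBat`.

Two leakage-relevant choices are deliberate:

* **Fold discipline.** In the benchmark, ComBat is refit on each
  training fold and held-out cases are transformed with the
  training-fold model. Transforming never requires labels.
* **Covariate protection.** By default no biological covariate is
  protected. When class and batch are associated, the batch means
  absorb class signal and unprotected correction removes it;
  `ComBatModel.fit(..., protect="label")` adds the class label to the
  estimation design (estimation only — the transform is unchanged), at
  the price of making the batch parameters depend on training labels.
  See *Limitations* for why no configuration makes harmonization beat
  raw features under strong class-batch confounding in within-cohort
  CV.

## Evaluation

Folds are stratified by label and grouped by case (every row/slice of
a case shares a fold), deterministic per seed. LR and SVM receive a
standardizer fit on training rows only; the tree ensembles consume raw
features. Hyperparameters come from frozen grids searched by inner
stratified 3-fold CV on AUC (`FAST_GRIDS` pins one point per model for
quick runs). AUC uses the Mann–Whitney construction with ties counted
½ and is undefined (NaN) when a class is absent. DeLong's test uses
the structural components V10/V01; when the estimated variance of the
paired difference is zero, p = 1 for identical AUCs and p = 0
otherwise, flagged `degenerate`. McNemar uses the continuity-corrected
statistic on discordant pairs; the χ² test is applied to the paired
correct/incorrect contingency. Threshold sweeps run on a 0.01 grid
with predictions positive at score ≥ threshold; the default operating
point is the largest threshold with sensitivity at its target (1.0),
the "miss no malignancy" rule.

## The CNN baseline

Topology: three blocks of [3×3 conv → batch-norm → ReLU → 2×2 max-pool
→ dropout], flatten, dense(32, ReLU), dropout, dense(1, sigmoid);
input 224×224 z-scored lesion crops (bounding box + 10% margin per
slice). Channel widths (4, 8, 16), dropout 0.25/0.5 and the training
recipe are this package's choices. The engine is pure NumPy with
explicit forward/backward passes (gradients are verified against
finite differences in scratch experiments at build time); im2col
convolutions keep a CPU epoch on ~150 slices under ten seconds.

Training uses class-weighted binary cross-entropy with SGD (momentum
0.9, lr 1e-2) by default; Adam is available but with a large ε (1e-3),
because at this scale classic Adam reproducibly collapses the net into
a constant-output state by silencing the dense layer. The same
collapse basin is occasionally reached from bad initializations, so
fitting monitors for a stall (≤ majority accuracy over six epochs) and
reinitializes, at most three times within the epoch budget.
Augmentation is flip/zoom ±10%/rotate ±15°/shift ±10%, label-
preserving and seeded. Slices never cross folds; a case's score is the
mean of its slice probabilities. Capacity checks (overfit a tiny set)
run with dropout and augmentation disabled, as is standard for that
diagnostic.

## The phantom cohort

What it emulates: two lesion classes differing only in internal
texture, imaged under batch-dependent acquisitions. Benign lesions are
randomly oriented ellipsoids (semi-axes 8–20 mm; 6–11 mm in the
scaled-down preset) of near-constant signal plus correlated Gaussian
noise with ~1 mm correlation length; malignant lesions add 3–8
hyperintense Gaussian nodules (σ 1.5–3 mm, amplitude 35·gap) and 1–3
hypointense septum-like planes (thickness 1.5–2.5 mm, amplitude
30·gap), gap = `class_texture_gap` (default 1). Batch effects are
applied to the whole image: nominal gain (1.0, 1.5), offset (0, 30)
and Gaussian blur (0, 1.5 voxels), with mild per-case gain/offset
jitter (log-normal σ 0.1; ±12) because sites sharing a technique do
not share one exact protocol. The noise is deliberately finer-grained
than the nodules so acquisition blur suppresses benign texture faster
than the malignant signal — the regime in which harmonization has
something to recover. `confounding` linearly skews each class's batch
shares (0 = exact independence by stratified construction, 1 = full
separation), with the malignant class skewed toward the
heavier-degradation batch.

Default cohort sizes follow the study setting (85 cases, 45 of them
malignant, 2 batches); tests and the acceptance script use the
scaled-down preset (40 cases, 48³-voxel grids) so the full suite runs
on one CPU in minutes. What the phantom does *not* model: MR physics
(coil profiles, k-space artifacts), anatomy outside the lesion,
segmentation variability, and any claim about true lipoma/ALT effect
sizes — the class gap is a free parameter, not biology. Passing tests
demonstrate the machinery is correct and the qualitative phenomena are
reproduced, not that clinical performance numbers transfer.

## Known limitations

* **Harmonization under strong confounding.** With class-batch
  alignment ~0.9 (confounding 0.8), any image-level batch effect is
  itself a class proxy: a perfect batch detector already scores AUC
  ≈ 0.9 under the tie convention, and tree ensembles additionally use
  proxy features to emulate per-batch thresholds. Unprotected ComBat
  removes the batch means — which then contain most of the class-mean
  signal — and label-protected ComBat at best ties the raw arm.
  Within-cohort CV therefore cannot show harmonization beating raw
  features in that regime. Even with balanced batches the in-cohort
  gain is cohort-dependent: a flexible tree ensemble can partly
  neutralize the nuisance on its own by conditioning on
  batch-indicating features, so across phantom replicates the
  harmonization gain ranges from nil to large (0.86 → 0.97 with
  DeLong p ≈ 0.049 in the worked example; near-zero average over
  other replicates). The unambiguous benefits — equalized batch
  means, protection of external generalization — are the ones the
  acceptance suite verifies directly.
* The four texture directions are in-plane with counts pooled over
  slices; a 13-direction 3D mode is not implemented.
* N4 bias-field correction is not re-implemented; callers may supply
  externally corrected volumes.
* The CNN is a deliberately small baseline; at phantom scale it is
  weak (as small from-scratch CNNs are on limited cohorts), and no
  transfer-learning arm is included.
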