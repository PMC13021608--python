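# Methods

## Problem and model

Brain-age models regress chronological age on structural T1 MRI and read
the gap between predicted and true age as a marker of accelerated or
decelerated aging. They assume globally intact anatomy, which gliomas
violate: the tumor and its edema would dominate any whole-brain feature
extraction. This package implements a lesion-aware variant:

1. **Brain Age Network (BAN).** A compact VGG-style 3D convolutional
   regressor whose stages consist of residual units (two 3×3×3
   convolutions plus a short-circuit connection); all spatial
   downsampling is done by stride-2 convolutions, never by pooling
   layers. Before the regression head, the network pools the feature map
   with **ROI-Align** over the bounding box of the non-lesion foreground:
   trilinear interpolation at sub-voxel sample points (2 per axis per
   cell, 8 per cell) mapped onto a fixed output grid, so the head input
   has constant size regardless of lesion volume. Voxels under the lesion
   mask (tumor core + peritumoral edema) are zero-filled after intensity
   normalization, and the ROI box is computed from the already-excluded
   image; together these make predictions *exactly* invariant to any
   intensity content inside the mask.

2. **Bias correction.** Brain-age predictions regress toward the training
   mean (young over-, old under-estimated). With (α, β) the OLS slope and
   intercept of predicted on chronological age Ω, fitted on the healthy
   training split, and MAE that cohort's mean absolute error:

       corrected = predicted + [Ω − (α·Ω + β)] + MAE

   On a noiseless linear cohort this removes the age-dependence of the
   gap exactly (corrected − Ω is the constant MAE for every subject).
   The MAE offset is kept as printed in the defining formula — it shifts
   every corrected age up by a constant and preserves lesion-driven
   deviations; `corrected_age(..., include_mae_term=False)` gives the
   plain correction for sensitivity analyses. The correction is frozen at
   fit time and applied as a fixed transform at inference.

3. **Brain Age Index.**

       BAI = (corrected − Ω) / (corrected + Ω)

   a dimensionless, scale-normalized deviation confined to (−1, 1),
   positive under accelerated aging, comparable across subjects of
   different ages (multiplying both terms by a constant leaves it
   unchanged).

4. **Epilepsy prediction.** Radiomic features from the lesion are passed
   through a selection chain — Mann-Whitney filter at raw p < 0.05 (no
   multiplicity correction at this permissive first stage), Spearman
   correlation pruning at |ρ| > 0.9 (strict; one representative per
   connected component, chosen by smallest filter p, then
   lexicographically), an iterative redundancy reduction, and L1-penalized
   logistic regression with λ chosen by 10-fold cross-validated minimum
   deviance (not the 1-SE rule). Two LightGBM classifiers (radiomic block;
   clinical block: age, tumor grade, BAI, sex) are tuned by random search
   over the grid {learning rate 0.01/0.05/0.1, leaves 31/63/127, depth
   5/7/10/−1, min data in leaf 20/50, L1 and L2 0/0.1/0.01, feature
   fraction 0.8/0.9/1.0}, maximizing mean AUC over a shared stratified
   5-fold split. Their out-of-fold probabilities — each subject scored by
   a model that never saw it — are stacked by logistic regression. The
   operating threshold is Youden's J on the training OOF probabilities,
   frozen before test evaluation.

## Training protocol

Adam (lr 0.001 default, weight decay 1e-6, β₁ 0.9, β₂ 0.999); loss is L1
weighted inversely to age-bin frequency (10-year bins by default,
weights normalized to mean 1, computable from a designated cohort such as
the glioma training set); the learning rate halves after 5 epochs without
training-loss improvement; training stops after 20 epochs without
validation-MAE improvement, restoring the best-validation weights. The
regression target is standardized internally (training-split mean/SD) so
the linear head operates at unit scale; predictions are mapped back to
years. Desk-scale runs use lr 0.01, which converges within ~15 epochs on
the phantoms; the protocol default stays 0.001.

The network is implemented directly on numpy (hand-derived backward
passes, verified against numerical gradients to ~1e-8 relative error on a
smooth loss). This keeps the package dependency-light and bit-reproducible
single-threaded; it is sized for desk-scale volumes (default 32³ at
2 mm), not GPU-scale cohorts.

## Synthetic cohorts

No clinical or public imaging data ships with the package; the phantom
generator produces cohorts carrying exactly the structure the framework
assumes:

* **Age signal.** A central ventricle-like dark sphere whose radius grows
  linearly with *effective age* (1.5 + 0.05 voxels/year, anti-aliased so
  the signal is continuous), plus a cortical-band intensity decline
  (0.3%/year), plus homoscedastic Gaussian voxel noise (SD 0.05 on a
  tissue intensity of ~1). Linear geometry was chosen because it is
  recoverable by a small network and verifiable in closed form.
* **Lesions.** Glioma phantoms get an ellipsoidal core (radii 2.5–5
  voxels) at a random off-center position, with an edema shell formed by
  2 voxels of binary dilation; core and shell alter the image intensity
  and define the mask. Placement is rejected (and resampled) if the mask
  covers more than a configurable fraction (default 10%) of the
  ventricle region, so lesion exclusion can never erase the age signal.
* **Aging perturbation and labels.** Glioma subjects receive an aging
  shift drawn around 15 effective years (jitter SD 3); the epilepsy label
  is Bernoulli with logit 1.0 − 0.5·[high grade] − 0.12·shift, and
  epileptic subjects' realized shift is then attenuated by the configured
  group difference (default to a mean of 8 years). The two configured
  shifts are therefore the generative group means, the label model is an
  explicit logistic in (grade, shift), and the planted ordering
  control < epileptic < non-epileptic holds by construction — mirroring
  the observed attenuation of apparent brain aging in glioma-related
  epilepsy. Defaults give ~26% epilepsy among glioma subjects and ~70%
  high-grade tumors, matching typical cohort composition.

What the phantoms do **not** emulate: MRI physics (bias fields, partial
volume, artifacts), registration error, multi-site intensity effects,
realistic anatomy, or nonlinear age trajectories. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes when that
structure is present — correctness and sensitivity, not clinical validity
on real data.

## Numerical and design choices

* **Normalization**: z-score over non-background (non-zero), non-lesion
  voxels; excluded voxels set to 0. The method behind "grayscale
  normalization" is not further specified upstream; the z-score makes the
  lesion-invariance property exact and is standard for CNN regression.
* **Resampling**: trilinear (`scipy.ndimage.map_coordinates`, order 1),
  output grid covering the input extent, edge-clamped.
* **Splits**: stratified 70/10/20 with largest-remainder rounding per
  stratum and a correction pass that makes the global sizes exactly match
  the largest-remainder targets while keeping each stratum within one
  subject of its quota. Strata smaller than 3 are merged into a neighbor
  with a warning.
* **Mask QC**: Dice on voxel overlap (both-empty defined as 1.0);
  ICC(2,1) — two-way random effects, absolute agreement, single measure —
  computed on per-subject lesion volumes from two raters, since only
  per-subject scalars support that estimand directly; CI by the
  McGraw & Wong F-bounds (cross-checked against pingouin).
* **Mann-Whitney U**: U = #{xᵢ > yⱼ} + ½·ties; exact p by enumeration for
  n₁+n₂ ≤ 12 tie-free samples, normal approximation with tie correction
  otherwise (via scipy).
* **Radiomics**: the upstream feature definitions are not published, so a
  compact fully-specified 19-feature set is implemented (11 first-order,
  4 shape, 4 GLCM at distance 1 averaged over the 13 unique 3D
  directions after 32-level equal-width quantization over the lesion
  range). Degenerate conventions: constant lesions have entropy 0, GLCM
  energy 1, GLCM correlation 1 (single gray level is perfectly
  predictable); the sphericity proxy uses the voxelized surface area.
  Externally computed feature CSVs flow through the same selection chain.
* **Redundancy reduction**: "preserve maximal descriptive power" is
  interpreted as a greedy rule — while any pair exceeds |ρ| 0.8, drop the
  feature with the highest mean absolute correlation to the rest. It is
  deterministic and idempotent; this interpretation is flagged as such.
* **AUC confidence intervals**: stratified bootstrap, 2000 resamples,
  percentile interval, seeded.
* **Determinism**: every stochastic step (init, shuffling, folds,
  search draws, bootstrap) is seeded; pipeline stage seeds derive from a
  single global seed via `numpy.random.SeedSequence`. Single-threaded
  numpy gives bit-reproducible runs, recorded in the run manifest with
  output checksums.

## Problem sizes

The bundled reference experiment uses 200 phantoms (100 controls, 100
glioma) at 32³ voxels with a (4, 8)-channel two-stage network, 18 epochs,
batch 16 — chosen as the smallest configuration at which the network
cleanly separates the planted effects (held-out control MAE of ~2 years
against a ~13-year mean-predictor baseline). Larger cohorts, deeper
networks and bigger volumes are a matter of configuration, not code.

## Known limitations

* Whether healthy controls and glioma subjects should be trained jointly
  is left open upstream; the default here trains on healthy subjects only
  (brain age ≡ chronological age there) and applies the model to glioma —
  joint training is available by passing a different training split.
* The MAE offset makes corrected − Ω positive on average even for healthy
  subjects; group *differences* are unaffected (it is a constant).
* The numpy network is CPU-bound: roughly 1.5 s per 16-volume batch at
  32³; it is a reference implementation, not a performance claim.
* ICC on per-voxel data, wavelet/filtered radiomics, calibration and
  decision-curve analysis are out of scope.
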