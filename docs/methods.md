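# Methods

`attrscint` implements a fully automated pipeline for detecting and
Perugini-scoring cardiac transthyretin amyloidosis (ATTR-CM) on total-body
planar bone scintigraphy, together with a digital-phantom world in which every
stage of the pipeline can be trained, tested and audited end to end on a
desktop CPU. This note records the models, the tunable parameters that matter,
the numerical choices, and what the synthetic experiments do and do not show.

## The clinical problem and the pipeline

Bone-avid tracers (99mTc-MDP/DPD/HDP/PYP) accumulate in amyloid-infiltrated
myocardium. The Perugini scale grades cardiac uptake visually from 0 (none) to
3 (myocardium brighter than bone). The pipeline automates two binary readings
of a planar study:

* **detection** — grade 0 vs grades 1–3;
* **severity** — grades 0–1 vs grades 2–3.

Stages, mirroring the clinical workflow:

1. **Localization.** Three single-structure 2D segmenters (left ventricle,
   whole heart, ribcage) run on the summation image. Each predicted mask
   drives a crop: LV bounding box + 70 mm margin, whole heart + 50 mm,
   ribcage + 1 mm. Margins are physical and converted to pixels by rounding
   `margin / spacing` per axis.
2. **Classification.** For each task, a binary CNN is trained per
   (fold, crop strategy, view) cell of a patient-wise 3-fold split with the
   three views anterior / posterior / summation — 27 models per task.
3. **Ensembling.** Probabilities are averaged in two stages: fold models
   within each (crop, view) group first, then the nine group means. The
   decision is the argmax; an exact tie resolves to the negative class
   (favoring specificity in a screening setting). For a balanced, complete
   grid the two-stage mean equals the flat mean of all members; the staging
   matters when the grid is partial.
4. **Interpretability.** GradCAM (pooled-gradient channel weighting at the
   last convolutional stage, rectified, bilinearly upsampled, min–max
   rescaled) and occlusion sensitivity (mean probability drop under a sliding
   zero patch, default 16×16 px with stride 8, fill value 0 = the
   post-normalization background) with thresholded binary overlays
   (default 0.5).

## Intensity conventions

Planar scintigraphy is not quantitative, so every image is normalized to its
own 99th percentile: clip to `[0, P99]`, divide by `P99`. The 99th percentile
(linear-interpolation quantile; the choice only perturbs the clipped tail) is
used instead of the maximum to resist isolated hot noise pixels.
Normalization is applied after cropping (`crop → resample to 2.8 mm →
normalize → letterbox`), so each classifier input is scaled to its own
content. Renormalization is idempotent only up to the interpolated quantile of
the clipped tail (observed gap < 1e-3 on smooth images).

The summation image is `anterior + mirror(posterior)` (left-right flip),
improving counting statistics. Posterior acquisitions are mirrored relative
to the anterior frame, so crops for the posterior view use the left-right
mirrored masks.

## The phantom world

No patient data ships with the package; a parametric 3D phantom generator
stands in for the clinical cohorts. Defaults: a 128³ grid at 2.8 mm isotropic
spacing (96³ is used throughout the tests; organs scale with the grid's
physical extent), an elliptical-cylinder torso of soft tissue (relative
intensity 1), a rib lattice and spine (8), two kidneys (10), a bladder (15),
and an ellipsoidal heart with blood-pool intensity 2 whose myocardial shell
(normalized ellipsoidal radius 0.35–0.80) is the LV. Organ positions/sizes get
a small seeded jitter per phantom. Counting noise is Poisson with the expected
total scaled to a per-view count (default 10⁶, the order of a routine
whole-body acquisition).

Cardiac uptake is parameterized by a fraction `f` of the uptake-free
projection's P99: LV voxel activity is set so the *mean* added signal over the
projected LV support equals `f × P99`. Per-grade intervals for cohort
generation are grade 0: `f = 0`, grade 1: `[0.1, 0.4)`, grade 2: `[0.4, 0.9)`,
grade 3: `[0.9, 1.5]` — spanning the same 5–150 % range as the uptake
augmentation. The mapping from visual Perugini grades to uptake fractions is a
modeling choice of this package; no quantitative mapping exists in the
literature the pipeline derives from.

Pseudo-planar projection is the plain sum along the anterior–posterior axis
(third grid axis by convention, validated): parallel-hole collimation has no
magnification, so one voxel column maps to one pixel and counts are conserved
exactly. Mask projection is the union along each ray; 3D masks are dilated
(ellipsoidal structuring element, per-axis radius `max(1, round(r/spacing))`
voxels) *before* projection when the 2 mm ground-truth dilation is requested.

**What the phantoms do not model:** attenuation, scatter, collimator blur,
anatomical variation beyond affine jitter, extra-cardiac uptake pathology,
or inter-patient tracer-level variability (organ intensity means are fixed).
Passing tests therefore demonstrate that the pipeline's machinery — not its
clinical accuracy — is correct; the phantom world is easier than any clinical
dataset.

## Uptake augmentation ("explainable augmentation")

A segmenter trained only on grade-0 images fails on images with cardiac
uptake. The remedy is simulating graded uptake inside the known LV mask of
grade-0 pseudo-planar images: an i.i.d. uniform texture on the LV support is
rescaled so its mean equals `fraction × P99(base)` and added. The level is
always computed from the *base* image (never the augmented one), so levels do
not drift. The default scheme takes 28 consecutive levels of the
5 %–150 %-in-5 %-steps grid (5 %…140 %); with the original included each case
yields 29 images, so 85 cases expand to 2465. The full 30-level grid is
available by configuration.

Class balancing for classifier training is a separate photometric/geometric
augmentation: random rotation (±10°), additive Gaussian noise (σ = 2 % of
P99) and horizontal flip, composed randomly until each class reaches the
target count; originals are always retained. The rotation/noise magnitudes
are this package's defaults.

## Networks and training

No GPU deep-learning stack is assumed: the networks are small CNNs written on
numpy with manual backpropagation (im2col convolutions, instance
normalization, ReLU, 2×2 max pooling, global average pooling, dense layers,
Adam). Gradient correctness is pinned by finite-difference tests.

* `unet_small` (segmentation): full-resolution conv stack
  1→8 (7×7) → 16 (5×5) → 8 (3×3) → 1 (3×3) with instance norm + ReLU between;
  receptive field ≈ 15 px ≈ 42 mm at 2.8 mm. Loss: Dice + foreground-weighted
  BCE (weight = background/foreground ratio, capped at 20 — small structures
  would otherwise be drowned out early). Binarization threshold 0.5.
  Sliding-window inference tiles with 50 % overlap
  (`n = ceil((L−p)/(p(1−o))) + 1` windows, evenly spaced, logits averaged);
  images smaller than the patch are zero-padded symmetrically and cropped
  back. Desk defaults: full-image patches, 10 epochs, batch 2, Adam lr 1e-2,
  ×0.95 every 5 epochs. The full-scale configuration (256×704 patches,
  100 epochs, batch 2, lr 1e-4) is retained for completeness.
* `cnn_small` (classification): three conv blocks (8/16/32 channels, 3×3,
  instance norm, ReLU, 2×2 pool) → global average pooling → dense softmax.
  Inputs are crops resampled to 2.8 mm, normalized, and letterboxed into
  96×96 (zero background; larger crops are downscaled preserving aspect
  ratio). Desk defaults: 20 epochs, batch 4, Adam lr 5e-3, ×0.95 every
  5 epochs; full-scale: 200 epochs, lr 1e-4. Each epoch records validation
  F1, sensitivity, AUC, specificity and accuracy; the checkpoint maximizing
  their unweighted mean is kept (ties → earlier epoch).

Training-fold validation is a patient-wise, label-stratified ~80/20 split.
All randomness flows from explicit seeds; single-threaded numpy makes runs
bit-reproducible.

The full-scale backbones named in the configuration enums (a Swin-UNETR-style
transformer and DenseNet-201) require a GPU autodiff framework and are
intentionally not implemented; selecting them raises an informative error.

## Metrics

Confusion counts come from argmax decisions; sensitivity, specificity,
precision, accuracy, F1 (harmonic mean of precision and sensitivity) and BAC
(arithmetic mean of sensitivity and specificity) follow. AUC is the
Mann–Whitney statistic of the positive-class probability (ties 0.5; computed
via `sklearn.roc_auc_score` and cross-checked against an all-pairs oracle in
the tests). The ROC sweeps all unique scores. A single-class label vector
yields a missing AUC with a warning. Rates with empty denominators are
reported as 0. The cross-validated evaluation scores each case only with the
nine models of the fold in which that case was held out, so no prediction
uses a model that saw the patient; the all-27-model ensemble is the
external-cohort mode.

## Problem sizes used by the test suite

Phantoms are 96³ (tests) or smaller; segmenters train on 10–20 image/mask
pairs; the end-to-end check uses a 60-patient cohort with balanced grades,
desk-scale training of all 54 task models, and reports held-out AUC per task.
The uptake-robustness experiment trains the same architecture with and
without uptake augmentation (a 6-level 25 %–150 % scheme keeps the expanded
set small) and evaluates on held-out grade-0 and simulated grade-3 phantoms.

## Known limitations

* Saliency on phantoms is *enriched* on the heart (GradCAM heart-region mass
  several times the uniform expectation; the occlusion peak falls on the
  heart) but does not concentrate entirely there: per-image P99 normalization
  couples LV uptake to the background level, so a correctly trained
  classifier also reads the globally dimmed background. The saliency tests
  assert enrichment and peak location rather than a majority-mass constant.
* The projected ground-truth mask edge corresponds to vanishing path length,
  so its rim has near-zero contrast; desk-scale Dice around 0.85–0.95 on
  phantoms reflects this intrinsic boundary ambiguity.
* Grade assignment in the cohort generator is per-patient (one acquisition
  per patient by default); reader variability, multi-tracer effects and
  scanner differences are not modeled.
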