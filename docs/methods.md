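# Methods

## Overview

`tumorshape` implements a tile-classification → region-morphology →
shape-feature → penalized-survival pipeline for pathology-style RGB
images, together with a synthetic cohort generator that makes every stage
testable against exact ground truth. This note records the models, the
parameter choices and their rationale, the numerical conventions, and the
limits of what the synthetic experiments demonstrate.

## Tiling and tissue masking

A slide is reduced to grayscale by the per-pixel channel mean and split
by Otsu's threshold, computed as an exhaustive scan of the 256 integer
candidates maximizing between-class variance (ties go to the lowest
threshold, so the split sits directly above the darker mode). Tissue is
the **dark** side of the split: H&E-stained tissue is darker than glass
background. A binary closing followed by opening with a disk
(`morph_radius`, default 1 pixel-radius at heatmap-cell scale) removes
pinholes and specks. A constant image has no valid split and yields an
empty mask plus a warning rather than an arbitrary threshold.

The patch grid covers `floor(H/s) × floor(W/s)` disjoint windows of
`s = patch_size` pixels; remainder pixels at the right/bottom edges are
dropped (no partial-window rule exists for non-overlapping tiling). A
cell is worth classifying iff strictly more than `tissue_fraction`
(default 0) of its pixels are tissue. A patch is *white* iff its mean
over all pixels and channels strictly exceeds `white_threshold`
(default 200 on the 0–255 scale; the value is configurable because it is
a property of the scanner/staining, not of the method). Patch
intensities are scaled to [0, 1] by division by 255 before
classification.

Dataset splitting is stratified per class with fractions (0.72, 0.08,
0.20) and the rounding convention *round-half-up for train, floor for
test, remainder to validation* — chosen because it conserves class counts
exactly; membership is assigned by seeded shuffle. Augmentation is the
flip group {identity, horizontal, vertical, both}.

## Patch classification

Classification is a contract: any model producing one probability row
per patch, non-negative and summing to 1 in the fixed class order
(tumor, non-malignant, white), deterministic and batch-order
independent, can drive the pipeline. The shipped reference classifier
computes seven summary features per patch (mean intensity, three channel
means, intensity SD, dark-pixel fraction below 0.5, blue-minus-red
balance) and fits a standardized multinomial logistic regression. This
is *not* a substitute claim about CNN accuracy on real slides; it is the
minimal probabilistic model that separates the synthetic textures, kept
deliberately cheap so the full pipeline runs in seconds. Hyperparameters
for an optional deep backend (batch 32, learning rate 1e-4, momentum
0.9, early stop after 10 stagnant epochs) are carried as configuration
keys and unused by the reference model.

Non-tissue grid cells are folded into the white class with probability
(0, 0, 1): only tissue windows are ever classified, and white is the
empty-region category. Argmax ties resolve by the fixed class priority
tumor > non-malignant > white (the class-order argmax).

## Region morphology

All region work happens on the heatmap grid (1 cell = 1 patch), with
**8-connectivity for both foreground regions and holes**. This matches
the measurement convention the pipeline standardizes on, at the cost of
the classical digital-topology paradox: a diagonal chain of background
cells can escape an apparently closed ring, so such configurations count
zero holes. The paradox is exercised and documented in the test suite
rather than "fixed", because consistency with the stated convention
matters more than topological elegance for relative, within-model
feature use.

Tissue samples are 8-components of non-white cells after a radius-1
closing (bridging single-cell classification gaps without changing gross
shape); samples with area strictly smaller than half of the largest
sample are discarded as fragments (areas measured after closing — the
cleanup defines the object, so the filter applies to the cleaned
object). Tumor regions are 8-components of tumor cells within a sample;
the largest is the main region, ties broken toward the earliest cell in
row-major order. Holes are 8-components of background inside the
region's padded bounding box that do not reach the pad frame.

## Shape features

Per-region geometry, all in heatmap-cell units:

- **perimeter** — crack convention: the number of unit cell edges
  adjacent to exactly one region cell. Exactly testable, rotation
  consistent, and gives the discrete isoperimetric bound P²/A ≥ 16 with
  equality iff the region is a solid square. A chain-code-weighted
  perimeter (skimage convention) is available via
  `perimeter_mode="chain"`; features are used relatively, so any one
  consistent convention is valid.
- **convex area** — hull of the four corners of every cell; a cell
  counts iff its center is inside or on the hull (so a single cell has
  convex area 1, and collinear cell runs are never degenerate).
- **moment ellipse** — population central second moments of cell
  centers; axis lengths are 4·√(eigenvalue); eccentricity
  √(1−(minor/major)²), defined 0 for a single cell; orientation is the
  major-axis angle to the column axis in (−π/2, π/2], 0 when isotropic.
- **extent** = area / bounding-box area; **solidity** = area / convex
  area; **filled area** = area + enclosed hole area.

The 22-feature vector per tissue sample: region count; sums over all
tumor regions of {area, perimeter, convex area, filled area, holes,
major axis, minor axis}; PA ratio of all regions computed as
(Σ perimeter)² / (Σ area) (one number per sample, matching the single
reported row; the alternative Σ(P²/A) is deliberately not the default);
and the main region's area, convex area, eccentricity, holes, extent,
filled area, axes, orientation, perimeter, solidity, mean tumor-class
probability, and PA ratio. Patients average their tissue samples
unweighted, across images. Samples without tumor regions are skipped
with a warning; patients without any usable sample are excluded.

Reporting scales live in one table (`FEATURE_SCALES`): per-1000 for the
pixel-sum features and PA ratios, per-100 for hole counts, per-0.10 for
the mean tumor probability, unscaled for eccentricity, extent, solidity
and the angle (no canonical unit exists for the angle, so it is exported
in radians unscaled). Scales are applied only at the model-input layer,
so raw geometry stays in natural units.

## Survival modeling

**Unpenalized Cox fits** use Newton–Raphson on the partial likelihood
with Efron (default) or Breslow tie handling, step-halving to keep the
likelihood non-decreasing, convergence when the largest coefficient step
falls below 1e-8 (max 50 iterations), and standard errors from the
inverse observed information. Monotone likelihood (perfect separation)
is *flagged*, not raised: either the step tolerance is never met, or the
information collapses and a standard error exceeding 1000·(1+|β|)
betrays the runaway. Wald p-values are two-sided; selection in the
univariate screen uses p ≤ 0.05 inclusive. Each feature is screened on
its reporting scale; constant or non-finite features are excluded with a
warning.

**The elastic-net Cox model** minimizes
`−(1/n)·loglik(β) + λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²)` with Breslow ties — the
1/n convention, so λ values interoperate with the wider glmnet
ecosystem. The solver is iteratively-reweighted cyclic coordinate
descent on the working-response quadratic model, with covariance
(Gram-matrix) updates and an active-set strategy in a compiled inner
loop; the λ path has 100 log-spaced values from λ_max (the smallest λ
with an all-zero solution, computed from the null-model gradient) down
to 0.01·λ_max (0.05·λ_max when n < p), solved warm-started in decreasing
order. λ = 0 runs the same machinery to the unpenalized optimum (the
quadratic subproblem with no penalty is Newton's method), which the test
suite requires to match the Newton Breslow fit within 1e-4. The mixing
parameter defaults to α = 0.5 — a genuinely open choice, split evenly
between ridge stability under the strong collinearity of the area-family
features and lasso sparsity.

**Cross-validation**: k = 10 folds, seeded and stratified by event
status (which guarantees events in every fold whenever there are at
least k events). The criterion is the Verweij–van Houwelingen held-out
deviance, `−2·(loglik_full(β₋ₖ) − loglik_without-fold(β₋ₖ))` summed over
folds along the shared full-data λ path; λ* minimizes the mean curve.

**Risk groups**: score = x'β̂ on the original feature scale; a cohort is
dichotomized at its own median (the cohort being plotted defines its
cutoff), strictly-greater scores going high, median-ties going low. A
null model (all scores equal) assigns everyone low with a warning.
Groups are compared by the Kaplan–Meier estimator and two-group log-rank
test (lifelines), and by a multivariate Cox model with covariates
high-vs-low risk, age (years, continuous), male-vs-female,
ever-vs-never smoking, and stage II/III/IV dummies against stage I
(Efron ties; empty stage levels drop their dummy with a warning).

## The synthetic cohort generator

The generator works at heatmap-cell granularity and renders to pixels,
so ground-truth region geometry is *exact by construction* — this is
what makes the feature-extraction acceptance tests exact rather than
approximate. One tissue sample is:

- a **tumor body** bounded by the radial function
  r(θ) = R·(1 + Σₖ aₖ·cos(kθ + φₖ)) on an ellipse of aspect ≥ 1, with
  harmonic amplitudes |aₖ| ∝ roughness/√k (larger k damped so boundaries
  wrinkle rather than shatter), clipped below at 0.3·R and reduced to
  its largest 8-component so the body is always one region;
- **holes**: single cells punched strictly interior (all 8 neighbors in
  the body) at pairwise Chebyshev distance ≥ 2, so each is a separate
  enclosed hole; a body too small for the requested holes raises an
  explicit error;
- **satellites**: single cells at Chebyshev distance exactly 2 from the
  body (disjoint under 8-connectivity, but inside the tissue rim),
  mirroring the observation that STAS fragments typically occupy a
  single patch;
- a **non-malignant rim**: the Chebyshev dilation of the tumor by 2
  cells, so holes read as non-malignant tissue enclosed by tumor and the
  whole sample is one tissue region.

Rendering draws class-conditional textures per cell: near-white noise
(mean ≈ 248) for white; pink ground with sparse dark-purple blobs for
non-malignant; darker ground with dense purple blobs for tumor. Default
`patch_size` is 32 rendered pixels per cell for desk-scale speed; 300
remains configurable to mirror full-scale slides. Every generator is a
pure function of its seed.

**Survival**: T = −ln(U)/(h₀·exp(x'β)) with U uniform — exponential
given the covariates, the canonical proportional-hazards generator.
Censoring is an independent exponential whose rate is solved numerically
(Brent) so that the *expected* censored fraction E[c/(c+hᵢ)] equals the
target `censor_rate`; a closed-form inversion does not exist once
hazards vary across patients. Defaults: cohorts of 150 (training) and
389 (validation) patients matching the emulated study sizes; hazard
driven by `pa_ratio_main` (β = 0.08 per PA unit) and `area_sum`
(β = 0.0017 per cell) — roughly half a log-hazard unit per SD of each,
a strong but plausible imaging-biomarker effect; baseline hazard
5×10⁻⁵/day putting median survival on a years scale; censor rate 0.3.
Clinical covariates (age ~ N(65, 8²), sex 50/50, smoking 60/40, stage
60/20/13/7) are independent of the hazard by default, so the adjusted
analysis tests that the image-derived risk group survives adjustment
against pure noise. Reported times are rounded to 0.01 days and floored
there, since a time of exactly 0 is invalid for the partial likelihood.

**What the synthetic experiments do and do not show.** They demonstrate
that the geometry is measured exactly, that the estimators recover known
parameters at the stated cohort sizes, and that the full pipeline
discriminates when shape genuinely drives hazard. They do not emulate
stain variation, out-of-focus tissue, red blood cells, macrophages,
necrosis, or annotation noise — the failure modes that dominate real
slide classification — so classifier accuracies on synthetic textures
say nothing about CNN accuracy on real H&E images, and no such claim is
made anywhere in the package.

## Numerical conventions and degenerate inputs

- Otsu ties → lowest threshold; constant image → empty mask + warning.
- Oversized patch window → empty grid + warning; white-threshold and
  screen comparisons are strict/inclusive exactly as stated above.
- Single-cell regions: moments all zero by convention.
- Main-region and area-filter ties: strict inequalities and row-major
  order, as documented per operation.
- Partial-likelihood evaluation shifts the linear predictor by its
  maximum before exponentiating (shift-invariant, overflow-safe).
- Coordinate-descent tolerance 1e-8 on the largest coefficient change;
  Newton tolerance 1e-8 on the largest step.
- The pipeline derives per-stage seeds from one master seed through
  `SeedSequence` spawn keys, so stages are reproducible independently;
  all numeric artifacts are byte-stable under a fixed master seed.

## Problem sizes used by the shipped experiments

Cohort-scale experiments run at the emulated study sizes (150 training /
389 validation patients, 20 replicate seeds) at label-map granularity,
where exact geometry is free; the rendered-pixel path (simulate → tile →
classify → heatmap → regions → features → survival) is exercised on
smaller cohorts (tens of patients, 8–32-pixel patches) because rendering
and window-by-window classification dominate runtime without adding
information about the statistics. Oracle suites use 200 random masks and
200 screening replicates.

## Known limitations

- 2-D only; no pyramid/whole-slide formats (plain rasters), no stain
  normalization, no overlapping tiling.
- The reference classifier is a texture-statistics model; swap in a CNN
  backend for real slides.
- With 8/8 connectivity, checkerboard-diagonal enclosures count no holes
  (see above).
- The elastic-net mixing parameter and the white threshold are
  conventions, not fitted quantities; both are exposed in configuration.
- Univariate screening before a penalized fit is the emulated design,
  not an endorsement; the selected set inherits the screen's multiplicity
  behavior (the type-I rate of the screen is itself tested).
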