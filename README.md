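# tumorshape

Tumor shape and boundary features from tile-classified pathology images,
with penalized Cox survival modeling — and a fully synthetic cohort
generator so the whole analysis runs on a laptop without any clinical data.

## The problem

In lung adenocarcinoma, the geometry of the tumor region visible in an
H&E-stained whole-slide image carries prognostic information: large,
irregular tumors with ragged boundaries and many satellite fragments
(tumor spread through air spaces, STAS) tend to predict worse survival
than compact, smooth ones. Quantifying this by hand is impractical — a
40X slide is tens of thousands of pixels on a side — so the standard
automated route is:

1. **Tile classification.** Slide the image into non-overlapping
   300×300-pixel patches, classify each as *tumor*, *non-malignant
   tissue*, or *white* (empty glass), and arrange the class probabilities
   into a heatmap with one cell per patch.
2. **Region morphology.** On the argmax label map, find the physically
   separate tissue samples (8-connected components of non-white cells,
   discarding fragments smaller than half of the largest sample), and
   within each, the 8-connected tumor regions; the largest is the *main
   tumor region*.
3. **Shape features.** For each tissue sample, measure 22 features:
   region count; sums over all tumor regions of area, perimeter, convex
   area, filled area, hole count, and major/minor axis lengths; the
   perimeter²/area (PA) ratio of all regions and of the main region; and
   the main region's area, convex area, eccentricity, hole count, extent,
   filled area, axis lengths, orientation angle, perimeter, solidity, and
   mean tumor probability. Features are averaged across a patient's
   tissue samples.
4. **Survival modeling.** Screen each feature with a univariate Cox
   proportional-hazards model (two-sided Wald p ≤ 0.05); fit the selected
   set with an elastic-net-penalized Cox model, choosing the penalty λ by
   10-fold cross-validated partial-likelihood deviance; score patients by
   the linear predictor x'β̂; dichotomize an independent validation cohort
   at its median score; compare the groups by Kaplan–Meier curves, the
   log-rank test, and a multivariate Cox model adjusted for age, sex,
   smoking, and stage.

Perimeter uses the *crack* convention (count of unit cell edges exposed to
background), under which P²/A ≥ 16 for any region with equality exactly
for squares — so the PA ratio is a scale-free boundary-roughness measure.

The deep network usually used for step 1 is deliberately a *contract*
here (`predict_proba(patches) -> (n, 3)` rows summing to 1): the default
backend is a multinomial logistic regression on color/texture summaries
that separates the synthetic textures essentially perfectly, and a CNN
can be slotted in unchanged.

## Worked example

Run the full study — synthetic training cohort (n=150) and validation
cohort (n=389) whose hazard is driven by the main-region PA ratio and the
total tumor area:

```python
from tumorshape.study import run_shape_prognosis_study

r = run_shape_prognosis_study(seed=1)
print(r.selected_features)        # 18 of 22 features pass the p<=0.05 screen
print(r.model.lam)                # 0.1368  (10-fold CV-chosen penalty)
print(r.n_high, r.n_low)          # 194 195 (median split of risk scores)
print(r.logrank_chi2, r.logrank_p)  # 57.99  2.63e-14
print(r.adjusted_risk_hr)         # 2.60
```

The fitted model keeps six nonzero coefficients (perimeter sum, convex
areas, PA ratios of all and of the main region, main perimeter) — the
boundary-roughness and tumor-burden families that truly drive the
simulated hazard. The validation split separates survival decisively
(log-rank χ² = 57.99, p ≈ 3×10⁻¹⁴), and the high-vs-low risk hazard
ratio remains 2.60 after adjusting for age, sex, smoking, and stage —
i.e. the image-derived risk group acts as an independent prognostic
factor in this simulation.

The same pipeline is available stage by stage from the shell, writing
plain-text artifacts (PNG slides, probability-map matrices, CSV feature
tables, JSON models) with per-stage manifests:

```bash
tumorshape all -o demo_run --seed 7 --n-train 30 --n-validation 40 --patch-size 8
cat demo_run/validation/validation.json
cat demo_run/report/summary.md
```

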