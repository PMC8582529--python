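# Methods

This note documents the models, conventions and numerical choices behind
`qfibrec`, in the order data flows through the package.

## Feature taxonomy

The 100-feature morphological grid is a reconstruction: the source
literature states the totals (100 morphological, 76 relativistic) and prints
a subset of names, but never enumerates the full list. Our grid is the
unique natural completion of the printed naming convention
`measurement + region letter (P/S/F; none = overlap) + pattern letter
(A/D; none = both)`:

* overlap cell: `SHG` (collagen area %) + 9 string summaries
  (`NoStr`, `NoShortStr`, `NoLongStr`, `NoThinStr`, `NoThickStr`,
  `StrArea`, `StrLength`, `StrWidth`, `StrOrientation`);
* each of portal/septal/fibrillar: 3 area features (total, `AGG`, `DIS`)
  plus the 9 summaries for the pooled, aggregated and distributed cells.

That totals exactly 100 and contains every printed morphological name. The
76 ratios are the 7 canonical per-cell ratios
(`NoShortStr/NoLongStr`, `NoThinStr/NoThickStr`, `StrLength/StrWidth`,
and the four category shares of `NoStr`) over the 10 cells, plus the six
area shares `{Portal,Septal,Fibrillar}{AGG,DIS}/total`; again every printed
ratio name appears. One published table row labels
`StrLengthSD/StrWidthSD` as a fibrillar feature although `S` denotes septal
in every other row; we treat it as septal-distributed, consistent with the
naming convention.

Zero denominators in ratio features map to 0 by convention, so a blank
sample yields an all-zero 176-vector rather than NaNs.

## Morphometry

* **Segmentation** (default, pluggable): global threshold at
  `mean + k*SD` (k = 2) of the image intensities, then removal of components
  smaller than 4 px. Computing the statistics over all pixels (not only
  nonzero ones) keeps the threshold between background and foreground for
  both noisy and noise-free imagery; the threshold is capped at the image
  maximum so constant-intensity foreground survives, which also makes the
  operator idempotent on binary input. Otsu thresholding is available as an
  alternative.
* **String length**: longest geodesic path through the component skeleton.
  Path steps use Kulpa's corrected weights (0.948 axial, 1.343 diagonal)
  because naive unit/sqrt(2) chain lengths overestimate Euclidean arc length
  by up to ~8% at oblique angles. The Euclidean distance-transform value at
  the two path endpoints is added, so a flat-ended ribbon of drawn length L
  measures ~L rather than L minus its width. On synthetic straight fibers
  this lands within ~5% of truth.
* **String width**: twice the mean distance-transform value along the
  skeleton, floored at one pixel (a component thinner than the pixel grid
  cannot measure below it).
* **Orientation**: principal-axis angle from second-order central moments,
  measured from the image x axis with y up, folded into [0, 180). The
  per-cell summary `StrOrientation` is the circular resultant length of the
  doubled angles (an anisotropy in [0, 1]); a mean angle is ill-defined when
  orientations are spread uniformly.
* **Pattern split**: a connected component is *aggregated* iff its area is
  at least `aggregated_min_area_um2`, else *distributed*.
* **Category thresholds**: long >= 20 um, thick >= 3 um, aggregated >= 300
  um^2 by default. The literature states that the categories exist but not
  their cut points, so these are configuration defaults chosen to sit
  between the synthetic generator's "short/thin fiber" and "long/thick
  fiber" regimes; boundary values belong to the upper class.
* **Regions**: real-tissue portal/septal/fibrillar classification is
  proprietary to the original acquisition system and is *not* reimplemented;
  region masks are an input (ground truth for synthetic samples,
  user-supplied for real images). A component is assigned to the region
  holding the majority of its pixels; components outside all masks count
  only toward the overlap cell.

## Synthetic image generator

Each sample is one tile mosaic (default 5x5 tiles of 512 px at 2 um/px — a
desk-scale stand-in for whole-section multi-mosaic scans; all geometry is
configurable). The three region masks are vertical stripes covering the
frame: deliberately schematic, but disjoint, covering, and sufficient to
test region-conditional measurement. Fibers are straight flat-capped
ribbons with uniform random length, width and orientation, placed by
rejection sampling so that no two structures touch (a 3 px dilation margin);
aggregate patches are ellipses with areas well above the aggregation
threshold, fibers well below it, so pattern ground truth is unambiguous.
The collagen channel adds Gaussian noise (clipped at zero); the
cell-structure channel is a smoothed random texture with holes at collagen
sites and is carried through I/O but unused by quantification.

What this does *not* emulate: curved or branching fibers, fiber crossings,
anisotropic illumination, stitching artifacts, and realistic portal-tract
geometry. Passing morphometry tests therefore demonstrate correctness of
the measurement operators on controlled input, not segmentation robustness
on real tissue.

## Synthetic cohort generator

Morphological features are monotone transforms (logistic for area
percentages and anisotropies, exponentials for counts and sizes) of
Gaussian scores sharing a per-patient "severity" factor (correlation 0.5 by
default), and ratio features are computed from the morphological columns,
so the table is internally consistent. The planted risk latent is a linear
combination of min-max-normalized planted features (default: six features
mixing direct and ratio terms), standardized, plus Gaussian noise
(sd = 0.3). Exactly `round(n * prevalence)` patients with the highest
latent are labelled early-recurrence (defaults: n = 64, prevalence 22/64).

Event times: early cases recur uniformly within (1.5, 11.5) months; other
patients either censor uniformly in (12, 60) months (probability
`censor_rate` = 0.2) or recur at 12 months plus an exponential whose
log-rate is linear in the latent. Overall survival adds an exponential
with latent-dependent rate and independent uniform censoring — the simplest
construction satisfying the proportional-hazards assumptions the evaluation
stage tests. AFP is lognormal around the 20 ng/mL decision point with its
Gaussian kernel correlated to the latent at `afp_corr` (default 0.2, i.e.
deliberately weak); MELD, stages, vascular invasion and tumor size are
sampled with mild latent dependence.

The generator returns the latent index as bookkeeping so tests can verify
recovery; it is not part of the modelled data. Inter-patient variability of
real fibrotic architecture is unknown — the planted-signal model is a
testing device, not a claim about study data.

## Index model

* **Normalization**: per-feature min-max to [0, 1], learned on the training
  table; constant features map to 0; unseen values clip to [0, 1].
* **Selection**: greedy forward selection minimizing ordinary least-squares
  RSS against the 0/1 early-recurrence label; ties break toward taxonomy
  order; candidates that make the design rank-deficient are skipped with a
  warning. The stop rule in the source literature is unstated; we take
  `k_max` from configuration with defaults 18 (combined pool), 8 (overlap),
  11 (portal), 11 (septal), 13 (fibrillar), plus an optional relative
  RSS-improvement stopping tolerance. The regression target is the 0/1
  label (linear, not logistic — matching the described construction).
* **LOOCV**: exactly n fold models; normalization and coefficients are
  refit inside every fold. Default mode `fixed_selection` chooses the
  feature subset once on the full data (mirroring the published
  description, which implies a single selected set); `nested` redoes
  selection per fold and is the unbiased variant. Both are first-class and
  the choice is recorded in the result object.
* **Degenerate designs**: fits use minimum-norm least squares. A
  rank-deficient design warns and names the offending columns (or raises
  with `on_singular="raise"`). This is what makes the constant-predictor
  limit well-defined: a constant feature normalizes to zero, the fold model
  reduces to its intercept, and each held-out prediction is exactly the
  mean of the remaining labels.
* **Published model**: the 18 printed coefficients with intercept 3.838,
  shipped with *identity* normalization because the training min/max were
  never published. Consequently it reproduces the printed arithmetic
  (all-zero vector -> 3.838; all-ones -> -3.237) but **cannot** reproduce
  the study's per-patient indices, which would require the original images.
* **Cutoff**: the published 0.501 ships as the default risk threshold, with
  a strict `>` rule (an index of exactly 0.501 is low risk). For retrained
  models the natural choice is the Youden-optimal cutoff from the training
  ROC, which `roc_auc` reports; the published cutoff-selection method is
  unstated.

## Outcome statistics

* AUC is computed by tie-corrected pair counting (Mann–Whitney form) and is
  verified in tests to equal the trapezoidal area under the ROC curve.
* Wilcoxon rank-sum: exact enumeration when min(n, m) <= 8 with no ties,
  otherwise the normal approximation with tie and continuity corrections.
* Kaplan–Meier and the log-rank test, and Cox proportional-hazards models,
  are computed with `lifelines` (Efron tie handling, Wald 95% CIs,
  Newton precision tightened to 1e-9). A monotone partial likelihood
  (perfect separation) is flagged `converged=False` with NaN estimates
  rather than reported as a number.
* Report rounding follows clinical-table convention: percentages to 1
  decimal, hazard ratios and CI bounds to 3 decimals.
* Early recurrence is a recurrence event with a disease-free interval under
  12 months; late and no recurrence are pooled as the negative class.

## Pipeline

`run_pipeline` executes simulate -> extract -> train -> crossvalidate ->
evaluate into a self-describing run directory (config hash, seed, artifact
list). The modeling path uses the cohort feature table, where the planted
signal lives; the imaging path renders a small number of demo mosaics
(default one 256 px tile) and extracts their features from pixels, so the
morphometric code runs end to end without making the run minutes-long.
Deterministic artifacts (features, model, scores) are byte-identical across
reruns with the same configuration.

## Problem sizes used in tests

Unit and acceptance tests run on one small mosaic (2x2 tiles of 256 px or a
single 256–384 px tile), 64-patient cohorts, 50-seed Monte-Carlo loops for
selection oracles and end-to-end discrimination, and 1000 permutations for
the log-rank size check. These sizes were chosen as the smallest at which
the checked properties are non-trivial and stable.

## Known limitations

* The feature grid and category thresholds are reconstructions (see above);
  numerical feature values are not comparable to the original system's
  output.
* The published model's identity normalization means its scores for real
  feature tables are on the wrong scale; retrain on your own cohort before
  applying the 0.501 rule to new data.
* Region classification of real tissue is out of scope; users must supply
  region masks.
* Synthetic imagery is schematic (straight fibers, stripe regions); no
  claim is made about performance on real SHG/TPEF scans.
* No competing-risk modelling; no regularized selection.
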