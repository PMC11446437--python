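# Methods

This note documents the models and procedures implemented in `cervtriage`,
the assumptions behind them, the default parameter choices, and what the
synthetic study conditions do and do not demonstrate.

## Problem setting

An ordinal three-class classifier (normal = 0, indeterminate = 1,
precancer+ = 2) scores cervical images for cancer-screening triage. The
package evaluates such a classifier's *generalizability* across capture
devices and geographies and its *test–retest repeatability* across repeat
images of the same woman, and quantifies how incremental retraining with
labelled images from a new device recovers lost performance. Because the
underlying image datasets are private, the pipeline ships with a synthetic
cohort generator and a trainable stand-in classifier that together
reproduce the statistical structure the methodology depends on; the
evaluation machinery itself is data-agnostic and accepts any cohort and
prediction tables in the documented CSV formats.

## Ground-truth adjudication

Classes are assigned per woman and inherited by all her images (summaries
count both levels). The rule engine is total and deterministic on its
precondition domain:

| facts | class |
|---|---|
| histology CIN3 / AIS / cancer | precancer+ |
| site in the >CIN2-only referral list | precancer+ |
| CIN2, hrHPV positive | precancer+ |
| CIN2, hrHPV negative | indeterminate |
| CIN2, hrHPV untested, not a >CIN2-only site | **error** (unresolvable) |
| < CIN2 or missing, expert review "normal" | normal |
| < CIN2 or missing, expert review "indeterminate" | indeterminate |
| < CIN2 or missing, no expert review | **error** (unresolvable) |

"≥ CIN3" is interpreted as {CIN3, AIS, cancer}. Sites whose referral
criteria guarantee >CIN2 disease (e.g. a LEEP-referral clinic) are
configured by name through `gt_cin2_only_sites`, not hard-coded.
Dataset summaries recompute every percentage as cell / grand-total;
externally printed percentage columns are never trusted or reproduced.

## Synthetic cohort model

Each image is a d-dimensional feature vector (default d = 8), a stand-in
for a CNN embedding:

```
x = class_mean + geo_shift + device_shift + woman_effect + image_noise
class_mean = (c - 1) · s · u_site ,   c ∈ {0, 1, 2}
```

* `s` = `class_mean_separation` (feature units; default 1.15): spacing of
  adjacent class means along the severity axis.
* `u_site`: unit severity axis. Seed devices use the global axis
  (feature 0); the new device's axis is rotated by 42° into feature 3
  (`severity_axis`), preserving the signal norm. This models a camera
  whose embedding encodes the same pathology along a partly different
  direction: a model trained on the old devices projects onto the wrong
  axis (out-of-the-box degradation), while a retrained model recovers the
  full signal. A norm-preserving rotation, rather than an attenuation, is
  deliberate: attenuation would cap attainable performance on the new
  device and retraining could never close the gap, which contradicts the
  geography-robustness phenomenon the pipeline is designed to exhibit.
* `device_shift`: large translation orthogonal to the severity axis
  (default magnitude 3.0), giving each device its own embedding cluster.
  A common translation of a test set does not change rank-based metrics
  for a linear model, so the cluster geometry and the out-of-the-box
  degradation are controlled by independent knobs (translation and
  rotation respectively).
* `geo_shift`: small translation per geography (default magnitude 0.5,
  directions orthogonal to the severity and device-bias axes), so device
  shift ≫ geography shift in feature space.
* `woman_effect ~ N(0, sw²)` (default sw = 0.4) is drawn once per woman
  and shared by all her images; `image_noise ~ N(0, sb²)` (default
  sb = 0.5) is independent per image. The within-woman intraclass
  correlation of any pure-noise feature is sw²/(sw² + sb²) ≈ 0.39. The
  per-feature noise scales default to 1 except 0.8 on feature 3: the
  rotated-axis coordinate is a slightly quieter embedding direction, which
  lets a jointly trained model recover the new-device signal in full.
* `noise_corr` (default 0) optionally correlates noise between the
  severity axis and the first device-shift axis; switching it on makes a
  seed-trained model lean on the shift axis, so the new-device translation
  then also biases its class calls toward higher severity. It is off by
  default because that coupling also makes part of the degradation
  unrecoverable by retraining.
* Repeat images per woman: {1: 0.10, 2: 0.45, 3: 0.30, 4: 0.15}
  (mean 2.5), consistent with external screening cohorts averaging two to
  three images per woman; the exact distribution of such cohorts is not
  published.

Default magnitudes were chosen by closed-form Gaussian AUC reasoning plus
small calibration simulations so that the default study conditions sit in
the informative regime: seed-test AUROCs near 0.95 (not saturated),
a clear out-of-the-box drop on the new device, full recovery once the new
device is represented in training, and stable limits of agreement. They
were frozen before the acceptance checks and are not tuned per test.

Diagnostic facts (histology, hrHPV, expert label) are drawn by inverting
the adjudication rules, so re-running the rule engine on a generated
cohort recovers the simulated classes exactly (a round-trip property
enforced in the tests).

The default *study structure* mirrors a published external-validation
design: a seed cohort of five studies on two legacy devices (~1500 women,
balanced classes) and an external cohort of six geographies on one new
device with site-dependent class mixes totalling 204/157/219 women (580
women overall, one site contributing only >CIN2 disease).

## Stand-in classifier

A multinomial logistic (linear softmax) model over image features — the
smallest trainable model that exhibits the phenomena of interest; no
convolutional architecture is simulated. Features are standardised with
training-set statistics frozen into the fitted results. The fit minimises
the multinomial cross-entropy with a small L2 penalty (default 1e-2 per
observation) by L-BFGS to tolerance 1e-8; the penalty keeps the optimum
finite on separable data. Optional class balancing subsamples *women*
(all their images together) without replacement to an N:I:P ratio before
fitting, seeded. Argmax ties break toward the lower class (the less severe
call). The severity score of a prediction is its expected class index.

## Experiment suites

**Heterogeneity comparison.** (i) train on a class-stratified 70% of the
seed cohort (woman-level split, 2:2:1 N:I:P balanced subsample), test on
the held-aside 30%; (ii) the same model, out of the box, on the full
external cohort; (iii) retrain on the seed training set plus the external
cohort minus one held-out geography (default Bolivia), test on that
geography. Each run reports classification metrics and Bland–Altman
repeatability.

**Incremental retraining.** Women from the external cohort are added to
the frozen balanced seed training set in nested increments
(n = 0, 5, 13, …, 70 precancer+ women; selections at increment j contain
increment j−1) at two ratios, 1:1:1 and 2:2:1 N:I:P; the model is refit at
every increment and evaluated on a fixed held-aside external test set and
on the seed test set (catastrophic forgetting). Nesting is deliberate:
independent redraws per increment would confound the learning curve with
selection noise. The n = 0 row *is* the out-of-the-box baseline — the
balanced seed subsample is frozen once and reused, so increments are purely
additive.

The held-aside external test set defaults to 230 women, the external class
totals minus the maximum training demand over both ratios at the largest
increment (204−140, 157−140, 219−70 = 64/17/149), drawn stratified by site
within class. This composition simultaneously makes every increment
feasible and maximises the usable training pool; proportional allocation
of 230 women would starve the normal/indeterminate pools at the largest
increments.

**Model panel.** For comparing many retrained models image by image: each
image's severity score is averaged over all models, images are sorted by
mean score within each truth class, and a fixed number per class (default
20) is drawn by quantile-stratified random selection — one image per
contiguous score bin — preserving the score distribution.

**Heterogeneity projection.** A 2-D embedding (PCA by default; UMAP
pluggable) plus a silhouette score per grouping axis quantifies the
cluster geometry: device separation is computed across all images,
geography separation within the new device only (geography is confounded
with device otherwise).

## Metric definitions and numerical choices

* AUROC: probability that a positive-class image outranks a negative one,
  midrank tie correction, ranking by the positive class's own softmax
  probability (the severity score cannot rank indeterminate-vs-rest
  monotonically). Computed at image level, matching image-level dataset
  summaries.
* Bootstrap CIs: percentile 2.5/97.5 over B = 1000 resamples drawn at the
  woman level; resamples that lose one of the two classes are discarded
  and counted (`n_boot_effective`). Test sets with a single class raise an
  error rather than returning NaN.
* Limits of agreement: centred on the mean per-woman maximum difference,
  half-width 1.96 × sample sd (n−1). With more than two repeats the
  "difference" generalises to max − min. Because published repeatability
  numbers do not always state whether "95% LoA" is the upper limit, the
  half-width or the full width, the report exposes all three. Women with
  one image are excluded and counted separately; fewer than two evaluable
  women is an error.
* Extreme disagreement: denominator is women with ≥ 2 images; a woman
  counts once however many extreme pairs she has.
* Plateau: the smallest increment whose AUROC is within 0.01 of the curve
  maximum (saturation is otherwise only qualitative).
* Determinism: a single master seed derives named sub-seeds
  (`numpy.random.SeedSequence`) for every randomised step; the run
  manifest records them. Two executions with the same master seed produce
  byte-identical tables.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* the methodology
assumes — ordinal Gaussian classes, device clusters dominating geography
shifts, woman-level repeat correlation, site-dependent class mixes — not
the content of real cervigram embeddings. Passing phenomena tests
therefore validates the evaluation machinery and the qualitative
shift/retraining behaviour of a linear classifier under these conditions;
it does not certify any real model's AUROC, nor reproduce published
real-data values, which depend on the original images and CNN. HPV assay
error, verification bias, reader adjudication dynamics and image-level
artefacts are deliberately out of scope.

## Known limitations

* The stand-in is linear; phenomena that depend on deep-feature
  nonlinearity (e.g. partial recovery of a rotated signal without any
  retraining) are outside its reach.
* A single linear model serving two devices at once must compromise
  between their severity directions, so the held-out-geography run sits
  slightly below the seed baseline on average; with the default 88-woman
  held-out geography its confidence interval is wide, and the
  CI-overlap comparison can fail for unlucky cohort realizations
  (observed in roughly 1 in 10 master seeds at default conditions).
* Bootstrap CIs at the woman level slightly undercover for the smallest
  test sets (a generic percentile-bootstrap limitation).
* The incremental curves use one nested selection per ratio; curve-level
  error bands across independent selections are not computed (they would
  require repeating the whole suite over master seeds).
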