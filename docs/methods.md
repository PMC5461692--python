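# Methods

`thyrocad` implements a computer-aided-diagnosis pipeline that separates
thyroid nodules from normal thyroid tissue on non-enhanced axial CT slices
using first-order texture statistics of a radiologist-delineated region of
interest (ROI). This note describes the model, the defaults and why they
were chosen, what the phantom generator does and does not emulate, and the
numerical conventions.

## Pipeline

1. **ROI definition.** A CT slice (HU-valued after
   `stored x RescaleSlope + RescaleIntercept`) is paired with a binary mask;
   the ROI is the *set* of pixels inside the mask. Although a masked image
   can be formed by multiplying image and mask, statistics are never
   computed on that product: outside pixels are excluded entirely, not
   carried as zeros, because every histogram and moment below is defined
   over the masked pixel multiset only.
2. **Denoising filter bank.** The full slice is filtered with 3x3 average,
   median and local-adaptive Wiener filters (edge replication at borders),
   then masked. Filtering precedes masking so that no artificial
   background value is blended across the ROI boundary. Feature columns
   are tagged by group: 1 = Wiener (W6), 2 = median (M6), 3 = average (A6),
   4 = unfiltered (`e1` = entropy under Wiener, `k3` = kurtosis under
   average, ...).
3. **First-order features.** Per ROI and filter group: entropy
   `e = -sum p(l) log2 p(l)`, uniformity `u = sum p(l)^2`, mean `m`, sample
   standard deviation `sd` (n-1 denominator), bias-corrected skewness `s`
   and bias-corrected *excess* kurtosis `k` (the Gaussian-reference term
   `-3 (n-1)^2 / ((n-2)(n-3))` included; no alternate convention offered).
   `p(l)` comes from a 256-bin equal-width histogram over the ROI's own
   min-max range by default (8-bit quantization is the de facto standard in
   first-order radiomics); a fixed [-1024, 3071] HU range is selectable.
   A 13-statistic GLCM (Haralick) feature set is available as a baseline;
   its "contrast" and "inertia" share one formula and are emitted under
   both names, documented as aliases.
4. **Normalization.** Per-feature min-max rescaling to [0, 1]
   (`Y = (X - min) / (max - min)`). Constant columns map to 0; values
   outside a fitted range clip to [0, 1] and are counted. By default the
   parameters are fitted on training folds only (leakage-safe); fitting on
   the full matrix is available to mirror a global-normalization protocol.
5. **Feature selection.** Sequential floating forward selection (SFFS) with
   a k-nearest-neighbour leave-one-out accuracy criterion (default k = 1,
   Euclidean distance on the normalized columns), run on a stratified
   selection split (default fraction 0.5) and re-scored, without refitting,
   on the validation split. All tie rules are pinned because subset search
   is sensitive to them: distance ties resolve to the lower sample index,
   vote ties to the normal class, criterion ties to the smaller subset and
   then to feature order.
6. **Classification.** The primary classifier is a soft-margin RBF-SVM
   whose (C, gamma) are chosen by stratified 5-fold grid search over
   C in 2^-5..2^15 and gamma in 2^-15..2^3 (multiplicative steps of 4;
   ties toward smaller C, then smaller gamma). Comparators: a Fisher
   linear discriminant (pooled within-class covariance, midpoint threshold,
   ridge fallback for singular covariance) and a one-hidden-layer
   feed-forward network (10 tanh units, linear output, trained as a
   regression onto +-1 targets with seeded L-BFGS up to 1000 iterations —
   a deterministic quasi-Newton fit was preferred over plain
   momentum-gradient descent for robustness on small cohorts; the optimizer
   is configurable).
7. **Evaluation.** Leave-one-out cross-validation in which *everything* —
   normalization fit, grid search, final fit — is redone inside each fold.
   Units are single images by default (matching a per-image protocol);
   holding out all images of a patient together is available because images
   of one patient are correlated and image-level LOOCV is optimistic.
   From the pooled predictions: SEN, SPC, PPV, NPV, ACC (nodule = positive
   class; a zero denominator yields 0 plus a flag), and ROC/AUC by
   threshold sweep with trapezoidal integration (ties contribute 1/2,
   equal to the normalized Mann-Whitney statistic). Report tables render
   at 3 decimals (half-up); full precision is kept internally.

## Phantom generator

The generator produces elliptical ROIs on 64x64 slices so the whole
pipeline is testable without clinical data. Design targets, in order of
authority: published per-class ROI-mean statistics, published qualitative
HU anchors, and a non-trivial classification surface.

* **Per-ROI mean attenuation** is drawn from truncated normals matching
  measured clinical cohort values: normal 89.491 +- 17.295 HU (bounds
  [40, 140]), nodule 68.851 +- 42.019 HU (bounds [-20, 160]). The classes
  therefore overlap in mean intensity — a uniform draw from the prose
  anchors ("around 90-120 HU" vs "below 70 HU") would make the mean a
  perfect separator and trivialize every downstream test.
* **Texture.** Tissue heterogeneity is a spatially correlated Gaussian
  random field (correlation length 2 px), scaled to a per-ROI texture sd
  drawn from U(4, 12) HU for normal tissue and U(12, 38) HU for nodules
  (centres at the 8 / 25 HU homogeneous-vs-heterogeneous anchors).
  Photon noise is *iid* Gaussian (default sd 5 HU) added everywhere.
  The scale separation is deliberate: a 3x3 filter suppresses iid noise by
  about a factor of three while largely preserving correlated structure,
  which is the premise of denoising before texture extraction. With iid
  texture instead, filtering would shrink signal and noise identically.
* **Lesions.** With probability 0.4 a nodule receives one water-like cyst
  (10 HU, disk radius U(2, 6) px); with probability 0.3, one to three
  calcification specks (300 HU, radius 1-2 px). These create the histogram
  tails that drive skewness/kurtosis and stretch the ROI range.
* **Surroundings.** The gland is embedded in a 4-px soft-tissue annulus
  (60 HU) before the air background (-1000 HU). Without it the 3x3 filters
  smear the air edge through the ROI rim (measured: median filtering
  inflated normal-class ROI sd from ~9 to ~20 HU), which no clinical slice
  exhibits — the thyroid borders muscle and vessels, not air.
* **Determinism.** Every phantom's RNG stream is spawned from the master
  seed via `SeedSequence`; a cohort is bit-for-bit reproducible, in memory
  or through the DICOM round trip (slope 1, intercept -1024, 1 HU
  quantization on disk).

An expected (and tested) consequence of ROI-min-max histogram binning:
*nodules show lower entropy and higher uniformity than normal tissue*,
because cyst/calcification outliers stretch the binning range and
concentrate the histogram mass, while homogeneous noise-dominated normal
tissue fills its narrow range nearly uniformly. This matches the direction
of the published cohort's normalized feature table. Nodule standard
deviation is higher, also as published.

What the phantoms do **not** emulate: anatomical thyroid shape, 3-D
context, partial-volume and beam-hardening effects, scanner-specific noise
spectra, and the correlation between lesion type and patient. Passing the
phantom study therefore demonstrates that the pipeline's machinery is
correct and directionally faithful, not that clinical performance would
match.

## Problem sizes and numerical choices

* The end-to-end phantom study uses 150 normal + 134 nodule images (the
  clinical cohort's class sizes) with nested grid search inside every
  LOOCV fold. The filter-bank noise experiment uses 50 + 50 phantoms per
  condition, a size at which the directional comparison is already stable.
* Histogram: rightmost bin closed; a constant ROI yields a single occupied
  bin (entropy 0, uniformity 1). `0 * log 0 := 0` throughout.
* Degenerate moments: `sd = 0` sets skewness and kurtosis to 0 with a flag
  rather than NaN so constant phantoms survive the pipeline; fewer than 4
  pixels is an error (the kurtosis denominator contains n - 3).
* Wiener filter: noise power is always estimated as the mean of the local
  variances (the classic `wiener2` convention); on a constant image the
  0/0 gain resolves to preserving the signal.
* The grid search's smaller-C tie-break interacts with label-permutation
  nulls: many grid points tie, the most regularized SVM wins, and a
  majority-voting SVM in balanced LOOCV opposes every held-out label
  (accuracy near 0). This estimator pathology is pinned by a dedicated
  test; permutation-null harness checks therefore use the LDA, whose
  midpoint threshold has a symmetric null.
* GLCM sum-variance is centred on the sum-average (not the sum-entropy
  variant of the original formula tables), and a constant ROI defines
  correlation as 1 by convention.

## Known limitations

* The filter-bank noise experiment shows no accuracy degradation at
  tripled photon noise under the default phantom: adding iid noise of sd
  `s` maps every ROI's total pixel sd `t` to `sqrt(t^2 + s^2)` — a
  monotone transform — so class separability carried by spread-tracking
  features survives any noise level, and the cohort-scale accuracy is
  already saturated. Demonstrating the denoising benefit on accuracy
  would require phantoms whose classes overlap heavily in spread, at the
  cost of the end-to-end accuracy contract.
* Image-level LOOCV with 2-3 images per synthetic patient is optimistic;
  patient-level grouping is provided but not the default, to match the
  per-image protocol.
* The Table-style "F value" in group-comparison reports is t^2 of the
  pooled test, recorded as such in the output metadata.
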