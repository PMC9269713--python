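# Methods

## Problem setting

Deep transfer learning for mammogram lesion classification typically freezes
a CNN pretrained on natural images and uses its penultimate activations as
features for a classical classifier. Two practical problems follow. First,
grayscale medical images are usually replicated across the three input
channels, wasting two of them. Second, the extracted features (1024–4096
wide) are strongly multicollinear, which destabilizes regression-type
classifiers. This package implements a pipeline that addresses both: a
pseudo-color input encoding, and a supervised PCA reduction ("LR-PCA") that
selects principal components by Wald significance in a logistic model
rather than by a retained-variance threshold.

## Pseudo-color encoding

Each grayscale ROI becomes a three-channel stack:

* channel 0 — the original intensities, untouched (bit-identical by
  contract);
* channel 1 — CLAHE (contrast-limited adaptive histogram equalization) with
  an 8×8 tile grid and normalized clip limit 0.01 (common defaults; both
  configurable). Constant patches pass through unchanged, since a
  single-level histogram has nothing to equalize;
* channel 2 — a linear percentile stretch saturating the bottom 1% and top
  1% of pixel values, with percentiles computed per image by linear
  interpolation of order statistics. If the two percentile values coincide
  the patch is returned unchanged.

Pseudo-coloring is applied at the native ROI resolution and only then
resized (anti-aliased bilinear) to the backbone's input side — this keeps
channel synthesis independent of the backbone choice. Intensities live in
[0, 1] as floats throughout; quantization to 8 bits (round-half-up) happens
only on write.

## ROI extraction and augmentation

Circle annotations (mini-MIAS convention: bottom-left origin, converted to
raster coordinates on use) are tiled with non-overlapping side×side squares
on a grid anchored at the circle's bounding square; a tile is kept only if
all four corners lie inside the circle, and tiles leaving the image are
dropped rather than padded (padding would fabricate tissue). Box
annotations (INbreast convention) yield a single whole-box crop resized to
the ROI side. Augmentation uses exact 90°-multiple rotations only by
default (`np.rot90` pixel permutations, no interpolation), giving exactly
4× the samples; left-right/up-down flips are opt-in and give 3 variants per
rotation (12× total). Rotations-only is the default because the benchmark
sample arithmetic (144 ROIs → 576 samples) matches ×4 exactly, while the
corresponding INbreast counts (107 ROIs → 1095 samples, ≈ ×10.2) match
neither ×4 nor ×12; the module exposes both settings and leaves the choice
to the caller.

## Backbone contract

The three supported backbones are used frozen, tapped before the
classification head: AlexNet (input 227², feature width 4096, ≈61 M
parameters), VGG16 (224², 4096, ≈138 M) and GoogLeNet (224², 1024 — the
global-average-pool output, forced by the width — ≈7 M). Parameter counts
are computed from explicit layer-shape tables of the standard architectures
(weights + biases, main branch only for GoogLeNet, whose auxiliary
classifiers are training-time scaffolding and vary across
implementations), so the contract is checkable with no deep-learning
framework installed. Running the real networks requires the optional
torch/torchvision extra; input standardization then uses the conventional
ImageNet per-channel mean/std.

The `fallback` extractor exists so the full pipeline runs offline: each
stack is downsampled to a fixed 24×24 grid per channel, flattened (1728
values) and projected by a seeded random matrix with orthonormal columns to
1024 features (the GoogLeNet tap width). The projection is deterministic
per seed and preserves inner products on its range; the width was chosen
because a much narrower random projection provably discards a proportional
share of any fixed discriminative direction's energy under isotropic
noise.

## LR-PCA

Given training features X (n×p) and binary labels y:

1. **Covariance PCA.** Eigendecompose the sample covariance (divisor n−1)
   of the mean-centered features — no variance scaling, matching the
   covariance formulation of the reduction. Components are ranked by
   |λ| (eigenvalue magnitude), ties broken by original eigen-index, and
   eigenvector signs fixed so the largest-magnitude entry is positive.
   The top K = 50 are kept (configurable). In *per-class* mode the PCA is
   fit on each class's rows separately (own mean, own covariance), the top
   ⌈K/n_classes⌉ components per class are concatenated in label-sorted
   order, and each component carries its own fitting mean, so the combined
   projection is a fixed affine map. Class-wise fitting preserves
   class-specific variance directions that pooled PCA can average away.
2. **Projection.** Score_j = v_jᵀ(x − μ_j) with μ_j the component's own
   fitting mean. On training data, pooled-mode scores are exactly centered
   and their covariance is diag(λ₁…λ_K) — multicollinearity removed by
   construction.
3. **Wald selection.** A binomial logistic regression with intercept is fit
   on the K training scores by IRLS (tolerance 1e-8 on the update inf-norm,
   at most 100 iterations). Standard errors come from the inverse observed
   information at the optimum, t = β̂/SE, and two-sided p-values from the
   standard normal reference — the standard Wald scheme for binomial GLMs.
   Components with p < α (default 0.05) are selected; the intercept never
   is. An empty selection is legal and the pipeline then falls back to all
   K scores.

**Separation handling.** When the classes are (quasi-)completely separable
in the score space — common with strong signals at moderate n — the
unpenalized MLE diverges and IRLS does not converge. The fit is then redone
with Firth's bias-reduced likelihood (Jeffreys-prior penalty via the
modified score U*(β) = Xᵀ(y − p + h(½ − p)), h the leverages), the standard
remedy that keeps estimates finite and Wald inference usable, and the fit is
flagged (`firth_used`). A tiny ridge penalty was considered and rejected: at
the penalized optimum of separated data the observed information collapses
to the penalty itself, making every SE ≈ 1/√ridge and every Wald statistic
≈ 0. Note that even Firth Wald tests lose power under complete separation;
on very easy problems the selection can come back small or empty, which is
why the empty-selection fallback exists.

Retained energy (the cumulative |λ| share of the top k components, per
fitting group) is exposed for diagnostics; it is reported against the full
spectrum of the source fit even after truncation.

## Multicollinearity diagnostics

Pairwise Pearson correlations over the first `max_features` columns
(default 200 — pair enumeration over the full 4096 width is needless for a
diagnostic), with two-sided p-values from t = r√((n−2)/(1−r²)) on n−2
degrees of freedom, a 10-bin histogram of p over [0, 1] (last bin
right-closed), and the fraction of pairs with p < 0.1. Constant columns
have undefined r and are excluded with a logged count. On genuinely
correlated deep features the histogram mass piles into the first bin.

## Classification protocol and metrics

Stratified 70/15/15 train/validation/test split (overall set sizes are
round(n·fraction); per-class quotas by largest remainder, with rounding
extras rotated across sets so every split stays balanced within one
sample), plus a stratified 5-fold partition of train+validation for
cross-validation; the test set never enters a fold. In CV the *entire*
LR-PCA reduction is refit inside each fold, so feature selection never sees
the held-out part.

The bank: decision tree (max depth ∈ {3, 5, 10, ∞}), linear and quadratic
discriminant analysis, SVM (linear and RBF, C ∈ {0.1, 1, 10}), KNN
(k ∈ {1, 3, 5, 7}, Euclidean), Gaussian naive Bayes, and a random-subspace
KNN ensemble (30 learners, subspace fraction 0.5, base k = 1, majority
vote) — the configuration that wins on the mammography benchmarks. Each
family is tuned on validation accuracy; ties go to the earlier family,
then the simpler setting.

Metrics come from the confusion matrix with the positive class defaulting
to *malignant* (or *abnormal*): Acc, SE (sensitivity), SP (specificity),
PRE, FNR = 100−SE, FPR = 100−SP, F1 = 2·PRE·SE/(PRE+SE), MCC, and AUC by
trapezoid over the score-threshold ROC (probability-like scores per family:
vote fractions for KNN-type models, posteriors for generative models, the
decision value for SVMs; ties share one ROC step, so a constant scorer
yields exactly 50). A single-class test set has no ROC and AUC is reported
missing. The FNR/SE and FPR/SP identities are enforced by construction;
where a published table row disagrees with its own identity (e.g. an FNR
printed as 0.58 beside SE = 99.62), the identity-consistent value is what
this package computes.

## Synthetic data

The generators define the study conditions for all tests.

**ROI images** (`RoiSimConfig`, defaults in parentheses): 32×32 patches of
Gaussian-smoothed white noise (σ = 4 px) rescaled to a mid-gray band
(0.42–0.58), plus a centered radial Gaussian lesion. Class cues mirror real
radiological ones: malignant lesions are larger (radius 0.42 vs 0.25 of the
patch side), higher-contrast (Δ = 0.40 vs 0.15) and spiculated (sinusoidal
rim perturbation, amplitude 5 px, 6 lobes, random phase); per-lesion
contrast jitter (relative sd 0.15) supplies the within-class intensity
variability without which class-wise PCA could not represent the
lesion-intensity direction at all (each class's PCA centers its own mean,
so a zero-variance direction vanishes from its covariance). Pixel noise
sd 0.03; everything clipped to [0, 1]; one seeded generator per call.

**Feature tables** (`FeatureSimConfig`): n = 400 samples, p = 200 features,
10 latent factors each loading on its own 20-feature group — planting
within-group multicollinearity — with geometrically decaying loadings
(1.5 × 0.8^j), mirroring the decaying covariance spectra of real deep
features and keeping eigenvalue gaps large against sampling noise so group
directions stay identifiable. Labels follow a logistic model on the first
3 factors with β = 21 each, putting the label model's Bayes accuracy near
98.5% — the accuracy regime the benchmark pipelines report. Feature noise
sd 0.25 keeps within-group correlations at 0.8–0.97. The ground-truth
informative directions are returned for recovery tests.

What the fixtures do **not** emulate: real lesion texture, film artifacts,
annotation noise, class imbalance, and inter-patient correlation between
ROIs tiled from one lesion. Passing tests therefore demonstrate the
machinery (oracle-correct decompositions and fits, leakage-free protocol,
calibrated type-I error, power against planted effects), not clinical
performance; benchmark-dataset accuracies require the real mammography
datasets and pretrained weights.

## Numerical choices and problem sizes

* PCA via symmetric `eigh` on the explicit covariance; agreement with an
  SVD factorization of the centered data to 1e-8 is enforced in tests.
* IRLS linear predictors are clipped at ±30 (beyond double-precision
  resolution of the logistic probability) to avoid overflow; Firth steps
  are damped to inf-norm ≤ 5.
* Wald p-values use the normal reference, reproducing the (SE, t, p)
  coefficient-table layout of binomial GLM software.
* Replicate-based properties (planted recovery, null selection rate) use
  100 seeded replicates at n = 400, K = 50; the end-to-end run uses 200
  ROIs per class. These sizes keep each suite to seconds-to-tens-of-seconds
  on one CPU while leaving the statistical margins wide.

## Known limitations

* Wald selection under complete separation is conservative even with the
  Firth fallback; the pipeline's empty-selection fallback (use all K
  scores) covers the degenerate case, but selection counts on very easy
  data are not meaningful.
* Per-class PCA blocks from classes with similar covariance structure
  produce strongly correlated score columns; the logistic fit then splits
  signal across near-duplicate columns and individual Wald tests lose
  power. This is a property of the method, not of the implementation.
* Multinomial (>2 class) selection, sparse/kernel PCA variants, and
  cross-validated choice of K or α are out of scope.
* The GoogLeNet parameter count depends on whether auxiliary classifiers
  are included; the reported 7 M covers the main branch only.
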