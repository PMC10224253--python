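# Methods

This note records the models implemented in `canopyseg`, the conventions
and defaults chosen where more than one reasonable option existed, and what
the synthetic data does and does not establish.

## Pixel features

Each 8-bit sRGB pixel is expanded to 24 features: the three channels of
RGB, HSV, YCbCr, CIELAB, YUV, CIELUV, HLS and CIEXYZ, in a fixed canonical
order that defines the feature-vector layout everywhere in the package.
Color science offers several variants of most of these spaces; for
bit-stable results the package fixes:

* CIELAB / CIELUV under the D65 white point (2° observer), as in
  scikit-image;
* YCbCr in the ITU-R BT.601 **full-range** (JPEG) convention, implemented
  directly as the 3×3 matrix — the studio-range variant would waste ~12 %
  of the encoding range on 8-bit data;
* hue channels carry the full 360° circle mapped to [0, 1];
* every channel is rescaled to [0, 1]: L by /100, Lab a/b via the
  conventional [−128, 127] byte encoding (neutral ≈ 0.5), YUV and Luv
  chroma axes by their documented extrema, XYZ by the D65 white point.

Normalisation to a common bounded range is required by the perceptron
(unscaled Lab a-values of ±80 would dominate the gradient); tree and kernel
models are indifferent to it, so one shared convention costs nothing.

Color-checker correction is intentionally minimal: white balance is a
per-channel linear gain mapping the mean observed gray tile onto the mean
reference gray, and hue calibration adds a per-group offset
(target − observed hue) to pixels whose hue lies in the group's angular
band, leaving saturation/value and achromatic pixels untouched. These are
the simplest transforms consistent with a 24-tile checker workflow; no
polynomial color correction is attempted.

## Vegetation indices

Per-pixel index images exist for ExG = 2G − R − B and
ExGR = ExG − (1.4R − G); both are thresholded with Otsu's method (values
linearly rescaled onto 256 bins, threshold maximising between-class
variance over all 256 candidates). ExGR is given the Otsu treatment rather
than the fixed zero threshold sometimes used in the literature, so the two
baselines differ only in the index.

Region indices are computed **from the mean R, G, B of the foreground
region** (and the HSV of that mean color), not as means of per-pixel index
values; a per-pixel-mean mode exists for sensitivity checks, and the two
agree exactly for the linear indices. All formulas operate on raw 8-bit
values; an optional chromatic-coordinate mode (r = R/(R+G+B), …) is off by
default because the printed index definitions are stated on raw channels.

Two indices deserve comment:

* **DGCI.** The canonical dark-green color index
  [(H−60)/60 + (1−S) + (1−B)]/3 is the default. An alternative literal
  parenthesisation (H−60)/[60+(1−S)+(1−B)]/3 — which compresses the value
  by roughly two orders of magnitude — is available behind
  `dgci_literal=True` / `--dgci-literal` for comparison.
* **GBRG.** As defined, (G−R)/(R−G) is identically −1 wherever R ≠ G and
  undefined at R = G. The formula is implemented faithfully; because the
  correlation table excludes constant predictors, GBRG can never enter the
  top-5 SPAD feature set, which is the sensible downstream behavior.
  Indices with vanishing denominators (GBRG at R=G, EGI at G=B) are flagged
  undefined rather than silently dropped.

## Patch dataset and splits

Annotated crops are standardised to 20×20 px by bilinear resize (the
interpolation perturbs pixel colors slightly; it is documented here for
that reason), so each patch contributes exactly 400 labeled feature rows.
Splits (3:1:1 for classification, 70:15:15 for regression) are seeded
permutations; part sizes follow the largest-remainder rule so they always
sum to the row count, and classification splits are stratified by label by
default, preserving class balance to within one row per part.

## Channel selection (DT-RFE)

A depth-bounded (default 12) Gini decision tree is fitted to the full
24-channel table; the lowest-importance channel is removed and the tree
refitted, one channel per iteration (the finest elimination granularity),
until one survives. Reported importance scores come from the initial
full-feature fit so they are mutually comparable; the elimination order is
kept separately, so both views are available. Selection keeps channels
with initial importance > 0.04 (the packaged threshold), or exactly top-k
on request. Ties in importance are broken by canonical channel order,
making the ranking reproducible per seed.

## Classifiers

**MLP.** One hidden layer (default 20 ReLU units, selectable by 10-fold
cross-validated grid search over {12, 20, 35, 60, 100}; ties go to the
smaller width), logistic output thresholded at 0.5, binary cross-entropy
loss, and plain mini-batch SGD — W ← W − a·∂E/∂W with defaults a = 0.01,
batch 256, 50 epochs, early stopping on validation loss with patience 5.
The implementation is plain NumPy so the update rule is exactly the stated
one; the ReLU subgradient at 0 is taken as 0. The weights with the best
validation loss are returned, and fixed seeds give bit-identical models.

**RF / SVM.** scikit-learn classifiers with the tuned settings used for
comparison: RF with 200 trees, max depth 20, min 4 samples per leaf, final
label from the averaged class probability at 0.5; SVM with RBF kernel,
C = 0.001, γ = 1 (both overridable from the CLI — this C/γ pairing is
unusually regularised and is kept as the documented tuning). SVM training
is capped at 100 000 rows by stratified subsampling with a loud warning,
since kernel fitting is quadratic in rows.

Repeated evaluation (`repeat_train`) re-splits and retrains per seed
(default seeds 0–99) and reports mean ± population sd of accuracy, F-score
and recall. Population (÷N) rather than sample sd is used throughout the
reporting, including mask-quality aggregation.

## Quality metrics

Qseg, Sr and Es are exact pixel counts via logical and/or/not: Qseg is
foreground IoU, Sr the fraction of the reference plant recovered, Es the
false positives relative to reference plant size (Es may exceed 1 for gross
over-segmentation; nothing clamps it). F-score at precision+recall = 0 is
defined as 0 and flagged. Images whose reference mask is empty are
excluded from aggregation with a warning, since Sr and Es are undefined
there.

## SPAD regression

Pearson correlations between each defined, non-constant region CVI and the
SPAD values rank the indices; the five largest |r| (ties by registry order)
become the predictors. The booster is stagewise least squares: the stage-0
model is the target mean, each depth-bounded regression tree fits the
current residuals, and the ensemble advances by learning_rate × tree.
Split finding is histogram-based: features are discretised onto 256 uniform
bins and trees see bin midpoints, which reproduces exact-split boosting
whenever bins exceed the number of distinct values (verified against a
handwritten exact-split reference and against an independent booster).
Hyperparameters are tuned on the validation partition over
n_estimators {100, 300} × depth {2, 3, 4} × learning rate {0.05, 0.1} ×
subsample {0.8, 1.0}. Adjusted R² uses the standard
1 − (1−R²)(n−1)/(n−p−1) with p = number of predictors, and is refused for
n ≤ p + 1.

## Synthetic scenes

The generator exists so that every stage is testable end-to-end with exact
ground truth. Plants are unions of rotated elliptical leaf lobes around
random centers — sufficient for color-based pixel classification, which
never uses shape. Leaf hue is drawn per leaf from N(mean, sd); the
glasshouse preset is a healthy green canopy (mean 115°, sd 8°) on textured
compost browns, while the field preset deliberately renders the hard case
the learned classifiers exist for: hue mean 80°, sd 26° (leaves spanning
green → yellow → brown, as under nutrient deficiency) over lighter soil
scattered with straw-yellow and stone-gray clutter ellipses. A linear
illumination gradient (default ±10 % glasshouse, ±18 % field) and additive
Gaussian pixel noise (sd 4 and 8 8-bit units respectively) are applied
after rendering; the truth mask records exactly the pre-noise leaf pixels.
All randomness flows through one integer seed.

Patch sampling takes 20×20 windows lying entirely inside (foreground) or
outside (background) the truth mask across freshly generated scenes, so
patch labels are pure by construction. SPAD cohorts space nutrient levels
evenly from deficient to healthy, interpolating the hue mean from 45° to
the preset's mean, and attach
SPAD = a + b·greenness + N(0, σ²), with greenness the mean ExG of true
plant pixels rescaled to [0, 1]. The defaults (a, b, σ) = (−190, 350, 1.5)
map the renderer's observed greenness span (≈0.55–0.71) onto a realistic
SPAD working range (≈5–60 meter units) with a repeatability noise typical
of handheld SPAD meters; they were fixed once from the renderer's geometry.

**What passing on synthetic scenes shows — and does not.** The scenes share
the real problem's structure (color-separable classes degraded by hue
drift, illumination gradients, clutter and noise) but not its texture:
leaves have no venation, specular highlights, shadows or occlusion
boundaries, and backgrounds have no moss, water reflections or plastic pot
edges. Accuracy figures obtained here therefore demonstrate that the
pipeline is implemented correctly and behaves in the expected order
(learned classifiers ≥ index thresholds as scenes get harder), not that a
given accuracy will transfer to any particular camera or crop. On real
imagery the patch-annotation and color-checker steps matter materially.

## Problem sizes and numerical notes

The test suite and the acceptance script run on deliberately small
instances chosen as representative desk-scale workloads: 192×192 scenes,
patch sets of 30–400 patches (12 000–160 000 pixel rows), SPAD cohorts of
n = 200, and 10-scene quality comparisons. Degenerate inputs fail loudly
by policy: constant index images (no Otsu threshold), empty regions, empty
references, single-class training data, zero-variance correlations and
n ≤ p+1 adjusted R² all raise rather than return placeholders. Ties are
always broken deterministically (canonical channel order, registry order,
smaller neuron count).
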