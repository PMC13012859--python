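# Methods

This note records the models implemented by `crferad`, the defaults
chosen where the methodology leaves a decision open, what the synthetic
phantoms do and do not emulate, and the package's numerical conventions.

## Synthetic phantoms

Each phantom is a single-channel 2-D slice with exactly one
4-connected lesion. The lesion support is a random ellipse
(minor/major ratio drawn in [0.6, 1]) deformed by three low-frequency
radial harmonics (amplitudes ≤ 6% each), rejection-sampled until the
equivalent diameter `d = 2√(area·s²/π)` lies in the configured interval
and the mask is simply connected. Defaults: 256×256 px at 0.5 mm/px
with lesions of 10–40 mm equivalent diameter. Scaled-down studies use
`scaled_phantom_config`, which switches to 1 mm pixels and caps the
diameter interval at 42% of the field of view so every lesion fits
(e.g. 10–26.9 mm at 64 px) — a problem-size choice, made once for all
scaled studies.

Intensities: background is white Gaussian noise (sd 0.2 by default);
the lesion adds a subtype-dependent mean shift (in units of the noise
sd), a correlated texture field (white noise smoothed at a
subtype-specific correlation length, rescaled to amplitude 0.25), and a
"low-gray zone" field that darkens a subtype-specific fraction of lesion
pixels by 80% of the lesion signal — a cartoon of hypo-intense
keratin-pearl/necrotic subregions. The three label bits map to three
image axes: histology → mean shift, cell size → texture correlation
length, keratinization → low-gray-zone fraction. No intensity statistics
for real subtypes are published, so these effect sizes are free
parameters of the phantom model; the defaults were set so that a
trivial within-mask mean statistic separates the two extreme categories
with accuracy > 0.9, the documented floor for downstream tests.
`strong_subtype_effects()` provides an amplified variant (larger mean
separations including a keratinization component, wider zone-fraction
spread) used by the recovery studies, which by construction need
clearly separable classes.

Clinical covariates (8 fields: age, HPV status, FIGO stage, nodal
metastasis, lymphovascular invasion, invasion depth, chemo- and
radiotherapy) are drawn from plausible marginals *independently of the
image and label*. This decoupling is deliberate: it makes "clinical
features are not retained by feature engineering" a testable property.
An optional flag couples invasion depth to lesion size.

What the phantoms do **not** emulate: 3-D anatomy, multi-sequence MRI
(T2WI/DWI/ADC), scanner artifacts, bias fields, multiple or infiltrative
lesions, and any real correlation between clinical covariates and
imaging. Tests passing on phantoms therefore demonstrate that the
algorithms are implemented correctly and can recover planted signal —
not that they reach clinical performance.

## Preprocessing

Resampling is linear for images and nearest-neighbor for masks, with
output extent `round(extent·s_src/s_tgt)`. Z-score standardization
rejects constant images. Augmentation draws one geometric transform —
rotation in ±15°, independent horizontal/vertical flips, isotropic
scaling in [0.9, 1.1] — applied identically to image and mask, plus
Gaussian noise (sd 0.01) on the image only; images are reflection-padded
and masks zero-padded so no lesion pixels are fabricated at borders.
Splitting assigns `floor(f·n)` subjects to validation and test and the
remainder to train, which maps 141 subjects at 0.70/0.15/0.15 to
(99, 21, 21); splitting is per-subject.

## Segmentation network

Encoder: three blocks of same-padded 3×3 convolution + ReLU + 2×2 max
pool (default 32/64/128 channels), so a 256×256 input yields a
128-channel 32×32 deepest map and a three-level skip pyramid.

Recurrent context: the deepest map is serialized row-major (column-major
is a config switch) into an H·W-long sequence of channel vectors and
passed through a bidirectional LSTM (256 units by default). The forward
and backward outputs are fused by **summation** and mapped back to the
encoder channel count by a learned linear projection — the fusion rule
is not prescribed anywhere, and summation keeps the block
shape-preserving with one extra projection; a symmetry test pins the
semantics (reversing the sequence while swapping direction parameters
reverses the output).

Position attention: with N = H·W positions and B, C, D learned 1×1
projections of the input A, the affinity `S_ji = softmax_i(B_i·C_j)` is
an N×N map (each row sums to 1) and the output is
`E_j = α·Σ_i S_ji·D_i + A_j`. α starts at 0, so the block is exactly
the identity at initialization and its influence grows during training.
The attention map is N×N, not C×N: only the pairwise-position reading
is consistent with "influence of position i on position j", and an
O(N²) brute-force oracle enforces it for N ≤ 16.

Decoder: three factor-2 bilinear upsamplings (separable interpolation
matrices, adjoint = transpose; bilinear-then-convolve avoids
checkerboard artifacts of transposed convolution), each followed by
concatenation with the matching skip (concatenation rather than
addition — the fusion rule being open, concatenation loses no
information) and a 64- then 32-channel 3×3 convolution; a final 1×1
convolution and sigmoid produce the probability map. An auxiliary 1×1
head on the attended context supplies deep supervision at the coarsest
scale.

Everything runs on a ~400-line numpy reverse-mode autodiff engine with
an Adam implementation; all operators are gradient-checked against
central finite differences to 10⁻⁵.

## Objective and schedule

Per-module loss = soft Dice (ε = 10⁻⁶) + mean binary cross-entropy
(predictions clipped to [10⁻⁷, 1−10⁻⁷]). The total is

    L = Σ_modules L_module + λ·Σ_global L_global + L_size

with two module terms by default (decoder head against the mask, the
auxiliary head against a max-pooled coarse mask), one global term
(batch-level Dice over all pixels, a spatial-consistency reading), and
λ = 1. The counts and λ are open parameters; the defaults are echoed
into every run log. L_size converts the summed probability mass to an
equivalent diameter and applies a squared hinge normalized by the
interval width: 0 inside [10, 40] mm (bounds inclusive),
`((d̂−bound)/30)²` outside; only "penalize outside the plausible range"
is prescribed, the squared-hinge shape is ours. The learning rate
follows one cosine cycle spanning all scheduled iterations
(η_max = 10⁻³ from the optimizer setting, η_min = 10⁻⁵ — unstated, set
two decades below), no warm restarts.

Early stopping monitors validation Dice (binarized at 0.5, matching
evaluation) with patience 10 and minimum delta 0.001, read as a
trailing window: stop when no epoch in the last 10 beats the best value
seen before that window by ≥ 0.001. A from-best-epoch reading is also
defensible; the window reading is implemented and oracle-tested.

## Segmentation metrics

Pixel-wise confusion counts give IoU, Dice, precision, recall,
specificity, accuracy and F1. Two IoU variants are reported —
foreground-only TP/(TP+FP+FN) and the mean of foreground and background
IoU — because the exact identity Dice = 2·IoU_fg/(1+IoU_fg) means a
(high IoU, mid Dice) pair can only arise from a class-averaged IoU;
callers must choose explicitly. MAE between probability map and mask is
reported both raw and ×100 (the common printed convention). Hausdorff
distance is the symmetric max-min Euclidean distance between 4-boundary
pixel sets, in px and mm, verified against an all-pairs oracle.

## Radiomics engine

Nine derived images: original; Laplacian-of-Gaussian at σ = 1.0 and
2.0 mm (σ converted to pixels via spacing, negated so bright blobs give
positive response, truncation 8σ so constants map to ~0); single-level
wavelet approximation (L) and summed-detail (H) reconstructions
(default `db2`, a 4-tap orthogonal wavelet; L + H reconstructs the
input); exponential, logarithm, square and square-root intensity maps
(shift-to-nonnegative rules keep domains valid). Features labelled
"3-D" in volumetric nomenclature are computed as their 2-D analogues —
the whole pipeline is 2-D — under the same names.

Masked intensities are quantized into a fixed number of equal-width
bins (default 32; fixed bin *width* would be the alternative, and the
choice is configurable). Matrices: GLCM at distance 1, symmetrized and
averaged over the four 2-D directions (making angle-averaged features
exactly invariant to 90° rotations); GLRLM summed over the same four
directions; GLSZM over 8-connected constant-level zones; GLDM with
α = 0, distance 1, dependence size = dependent neighbors + 1; NGTDM
from the 8-neighborhood mean. Degenerate single-level regions return
defined values (entropy 0, correlation 0, finite everything). Feature
formulas follow the conventional radiomics definitions at the standard
cardinalities 24/16/16/14/5 per family and 18 first-order statistics;
only the catalogue *totals* per family are externally fixed
(216/144/144/126/45/162), and those totals force exactly these per-image
counts across the 9-filter bank. The histogram family names only the
median explicitly; the other eight (mean, mode, variance, skewness,
kurtosis, energy, entropy, IQR) are a documented stand-in that
completes the count of 9. The catalogue totals
8 + 14 + 9 + 9·(18+24+16+16+14+5) = 868 entries.

Shape features (14) use region-property moments with the Crofton
perimeter estimate (accurate to ~1% on disks of radius ≥ 20 px);
elongation/flatness use the √(eigenvalue-ratio) convention, which for
an ellipse equals the minor/major axis ratio. All texture matrices are
property-tested against brute-force pixel/pair/run/zone enumeration.

## Selection

Standardization is fit on training subjects only (constant columns
dropped with a warning) and reapplied to held-out data. Three rankings:
impurity importance from a seeded 200-tree forest; per-feature one-way
ANOVA F (an infinite F from a perfect separator is capped at 10× the
largest finite score before normalization); RFE around a forest,
eliminating 10% of the feature count per iteration (step unstated;
10% balances cost and granularity). Scores are normalized to sum to 1.
The ensemble fuses by mean reciprocal rank — the combination rule is
not prescribed; MRR is scale-free and insensitive to heavy-tailed score
distributions. The retained count searches 5–100 (step 5) by
stratified-CV forest score, choosing the smallest count within one
standard error of the best ("optimal" is unspecified; 1-SE prefers
parsimony). A final cutoff keeps features with normalized importance
≥ 0.01, capped at 30. The correlation report uses Pearson r with
average-linkage clustering on 1 − |r|.

## Pathological typing

Labels: category = 4·cell_size + 2·keratinization + histology (0–7).
SMOTE is applied to training folds only: each minority class is raised
to the majority count with convex combinations `x + u(x_nn − x)` of
same-class nearest-neighbor pairs (k = min(5, n−1)); originals are kept
verbatim; singleton classes raise. Classifiers: random forest (grid
n_estimators ∈ {50,100,200,300}, max_depth ∈ {None,10,20,30},
min_samples_split ∈ {2,5,10} — 48 combinations), XGBoost, SVM and
logistic regression, each tuned by exhaustive grid search under
stratified 5-fold CV on macro-F1 (the averaging mode and selection
metric are unstated; macro treats rare categories on equal footing, and
accuracy is available via config). Evaluation computes the confusion
matrix over the union of train/test classes; per-class one-vs-rest
precision/recall/F1; macro averages over classes with nonzero test
support. A category absent from training is structurally never
predicted, so its recall is 0 — reproduced as a property. ROC curves
are one-vs-rest with trapezoidal AUC; a single-valued truth vector
yields an explicit "undefined" rather than a fabricated number.

## Problem sizes in tests and the acceptance script

Scaled-down studies use 64×64 phantoms: segmentation learning uses 40
noiseless phantoms and a 8/16/32-channel network with 32 recurrent
units (validation Dice ≈ 0.96 in ≤ 30 epochs); selection recovery uses
50 replicates of 5 planted 1-SD features among 95 noise features with
n = 200; typing recovery uses 300 phantoms over three imbalanced
categories with the strong-effect configuration. These sizes are the
package's chosen study conditions; all randomness flows from a single
seed through per-stage derived seeds.

## Known limitations

- The numpy network is CPU-bound and intended for small studies; it is
  a faithful implementation, not a performance port.
- 2-D only; no multi-sequence fusion; no pretrained weights.
- The radiomics engine implements exactly the catalogue described
  above, not the full generality (arbitrary distances, resegmentation,
  standard-compliance certification) of large radiomics toolkits.
- Phantom effect sizes are free parameters; absolute classification
  numbers on phantoms say nothing about clinical cohorts.
- Nested cross-validation (for unbiased generalization estimates of the
  tuned classifiers) is out of scope.
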