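# Methods

`echotex` implements a complete comparison framework for discriminating
hepatocellular carcinoma (HCC) from the surrounding cirrhotic parenchyma
(PAR) in B-mode liver ultrasound patches: annotation-driven patch
generation, a 47-feature conventional texture pipeline with feature
selection and four classical classifiers, a multi-resolution
atrous-spatial-pyramid-pooling (ASPP) convolutional network, and a shared
evaluation layer. Clinical ultrasound recordings cannot be redistributed,
so the package ships a seeded speckle-phantom generator that emulates the
statistical contrast between the two tissue classes; every claim the test
suite makes is a claim about those phantoms, not about patients.

## Patch generation

Tumors are annotated as polygons ((x, y) = (column, row), 0-based, even-odd
interior). A raster-order, stride-1 greedy scan over all 56x56 windows
accepts:

* **HCC**: the window lies fully inside the polygon and its
  intersection-over-union with every previously accepted window is below
  0.1%;
* **PAR**: the window lies fully outside, has at least one corner on the
  rasterized polygon outline (1-pixel tolerance — exact incidence on float
  vertices is measure-zero), and its intersection with every accepted
  window is below 0.1% of its own area.

The traversal order is not dictated by the acceptance rules themselves; we
fix row-major scanning with greedy acceptance so the output is
deterministic, and verify in tests that the implementation (which skips
dead candidates wholesale for speed) is bit-identical to the literal
brute-force scan. The HCC bound is relative to the *union*, the PAR bound
to the window's *own area*; the asymmetry is implemented as stated.

Augmentation draws from the pool {rotations every 5° in [-45°, 45°]} x
{zoom 0.8, 1.0, 1.2} x {identity, horizontal reflection}. The pool holds
113 non-identity combinations but the training-set bookkeeping requires a
x10 multiplier, so each patch yields the original plus nine seeded draws
without replacement. Rotation and zoom use bilinear interpolation with
reflect padding, center-cropped or reflect-padded back to 56x56.

Dataset splitting is stratified by class, or grouped by patient
(default) so no patient contributes to two partitions; grouped splits meet
the requested proportions as closely as whole patients allow.

## The 47-feature texture descriptor

Each patch is median-filtered (3x3, reflect borders) before feature
extraction. The canonical inventory, in fixed order:

| family | n | notes |
|---|---|---|
| order-2 co-occurrence | 6 | homogeneity, energy, entropy, correlation, contrast, variance; mean over the 8 unit displacements at multiples of 45° |
| order-3 co-occurrence | 6 | same statistics on gray-level triples; mean over 12 direction pairs (4 collinear + 8 right-angle, the center pixel central), component offsets ±2 |
| autocorrelation | 1 | Σ I(x,y)·I(x+1,y+1) / Σ I(x,y)² over the common (H−1)×(W−1) support |
| Hurst index | 1 | increment-scaling exponent, clipped to [0, 1] |
| edge statistics | 3 | Sobel + Otsu threshold: edge frequency, mean edge magnitude, circular-mean orientation in [0, π) |
| Laws energy | 10 | density (mean |response|) and frequency (fraction above the mean) of the L5/E5/S5/W5/R5 maps |
| wavelet entropies | 20 | Shannon entropy of all 4 first-level + 16 second-level Haar components |

Choices the literature leaves open, pinned here:

* **Quantization.** Order 2 uses 32 gray levels, order 3 uses 16 (a 16³
  tensor stays tractable and non-degenerate on 56x56 patches). Both
  configurable.
* **Order-3 statistics.** Contrast/homogeneity use the mean pairwise
  squared level difference over the three tuple pairs; variance averages
  the per-position central moments; correlation averages the three
  pairwise correlation coefficients. Zero-variance marginals contribute a
  correlation of 0.
* **Wavelet entropy normalization.** Coefficient magnitudes are
  L1-normalized per component, so the sum is a proper (scale-invariant)
  Shannon entropy; the literal unnormalized sum is available behind a
  flag.
* **Laws bank.** The five standard 1-D vectors; each micro-structure
  vector is paired with the smoothing vector L5 (and L5 with itself for
  the level map).
* **Hurst estimator.** Slope of log mean |increment| vs log lag over lags
  1..8, horizontal and vertical increments pooled. A constant patch is
  defined as maximally smooth (H = 1). On synthetic fractional Brownian
  surfaces (spectral synthesis, 64x64) the estimator recovers H in
  {0.3, 0.5, 0.7} within ±0.15 on average; a small negative bias at high
  H is inherent to increment estimators at this patch size.
* **LBP.** 8 neighbors at radius 1 (bilinear interpolation), strictly
  brighter-than-center bits, per-cell 256-bin histograms over 14-pixel
  cells; border pixels without a full neighborhood are skipped. The
  difference to the center is interpolated (rather than the neighbor
  value) so equal-valued neighborhoods give an exact zero code.

Degenerate inputs never throw: empty edge sets, zero denominators and
zero-variance distributions all map to documented constants, and all 47
outputs are finite for every 8-bit input.

## Feature selection

Four selectors, then the union:

* **CFS merit** k·r̄_cf / √(k + k(k−1)·r̄_ff) (point-biserial feature-class,
  Pearson feature-feature, zero-variance → 0), searched by a genetic
  algorithm;
* **consistency** 1 − Σ(pattern count − majority)/n over equal-frequency
  10-bin discretized patterns, same GA;
* **information gain** and **gain ratio** over entropy/MDL-discretized
  features, keeping scores above 0.3 bits (raw bits, not normalized).

The GA uses bit-mask chromosomes, population 20, fitness-proportionate
selection, single-point crossover (p = 0.6), per-bit mutation (p = 0.033),
one elite, 20 generations — the defaults of the classical toolkit this
mirrors, with only the generation count prescribed. Consistency is
monotone under adding features, so its best subset tends to be large; the
union is therefore inclusive rather than minimal, which is the stated
semantics. Feature names are processed in sorted order so the result is
invariant to column order.

## Classical classifiers

scikit-learn estimators behind a fixed protocol: linear SVM (degree-1
polynomial kernel, C = 1, min-max normalized inputs, Platt-scaled
probabilities), random forest (100 trees), AdaBoost (100 rounds over
entropy-criterion trees with mild cost-complexity pruning, α = 0.001,
min leaf 2 — standing in for classic pruned C4.5 trees), and an MLP
(SGD, learning rate 0.2, momentum 0.8, 500 epochs) whose hidden topology
is chosen from {1, 2, 3 layers} × {a, a/2, a/3} nodes,
a = (n_features + n_classes)/2, by accuracy on an internal 90/10 split of
the training portion. Evaluation uses a stratified seeded 80/20 split;
HCC is the positive class.

## The multi-resolution ASPP network

Input: one grayscale 56x56 patch. Two multi-resolution blocks of parallel
3x3/5x5/7x7 convolutions (half-kernel padding preserves resolution;
outputs concatenated), each block followed by a shortcut concatenation
with its input and 2x2/stride-2 max pooling; then an ASPP module at 14x14
with five branches (1x1 convolution; 3x3 dilated convolutions at rates 2,
3, 4 with padding = rate; global average pooling → 1x1 convolution →
upsampling), concatenated to 5·NF3 channels and fused by a 1x1 convolution
to NF3 with batch normalization and dropout (rate 0.5, configurable);
finally a single fully connected layer to 2 logits with softmax
cross-entropy. Every convolution is followed by ReLU then batch
normalization — that wording is followed literally, with a flag for the
conventional conv-BN-ReLU order. Weights are Glorot-uniform initialized.

Channel arithmetic: the input shortcut contributes its own channel count,
so the concatenations give 3·NF1+1 at 56x56 and 3·(NF1+NF2)+1 at 28x28;
pooling preserves channels. `shape_report` measures the chain by probing a
built model rather than re-deriving it on paper.

The layer stack is implemented in numpy (float32, channels-last):
convolutions run as one GEMM over an im2col matrix when C·k² is small and
as a loop of per-tap GEMMs otherwise; upsampling a 1x1 pooled map is an
exact constant broadcast; max-pool ties resolve to the first cell in scan
order. Backward passes are verified against finite differences per layer
and against the directional derivative for the full model. Training is
plain SGD with momentum (default: learning rate 1e-4, momentum 0.1, batch
64, 100 epochs), per-epoch validation accuracy recorded, and the
best-validation epoch restored as the final model. All randomness —
initialization, batch order, dropout — flows from integer seeds.

## Evaluation

Confusion counts with HCC positive; accuracy, sensitivity, specificity
with undefined ratios flagged rather than crashed. AUC is computed exactly
via midranks (ties count one half), equivalent to trapezoidal ROC
integration, and checked against brute-force pairwise counting.
Confidence maps score a sliding 56x56 window (default stride 14, plus the
last fitting row/column so borders are covered) and average overlapping
windows per pixel; the overlay renders HCC probability red and PAR green.

## The phantom generator

Fully developed speckle: a complex circular-Gaussian scattering field is
Gaussian-blurred at `correlation_length` (the PSF scale; larger = coarser
grains), its envelope magnitude is multiplied by a smooth gain field of
relative amplitude `heterogeneity`, log-compressed, standardized and
mapped to 8-bit gray levels around `mean_brightness` with a fluctuation
std of about 30·`contrast_scale`. A lesion is composited inside a polygon
(auto-ellipse by default, ≥56-pixel margins so both classes yield valid
patches) with a ~2-pixel blended border emulating the diffuse tumor
margin. Cohorts jitter texture parameters per patient (±8% correlation
length, ±6 gray levels brightness, ±15% heterogeneity) under a splittable
seed sequence.

When the inside and outside parameters are identical the generator emits a
*single* realization with the polygon drawn on it: blending two
independent realizations would leave a faint seam along the border that
classifiers can detect, and the null phantom's contract is the absence of
any class signal. The same rule makes cohort jitter shared in the null
case.

What the phantoms do **not** emulate: attenuation with depth, focal-zone
dependence, device post-processing, anatomical context (vessels,
capsule), or the absolute intensity statistics of any scanner. Passing
tests demonstrate that the pipeline is mechanically and statistically
sound, not that its clinical figures transfer.

## Study conditions and problem sizes

The standard experiments (in `echotex.workflows`, shared by the test
suite and `scripts/acceptance.py`):

* **Separable study** — 20 patients × 5 frames (400x400), lesion
  correlation length 4 vs background 1.5; per-patient class-balanced
  subsampling capped at 2,000 patches, patient-grouped 80/20
  train/validation. The network runs the scaled configuration
  NF1 = NF2 = NF3 = 16 for 10 epochs with the published optimizer
  settings; the conventional route trains a 100-tree random forest on the
  47 features of the same patches. Both routes separate the classes
  essentially perfectly (validation AUC ≥ 0.99 in our runs).
* **Null control** — 12 patients × 3 frames with identical textures;
  the four classical methods at full scale on a stratified 50/50 split
  (large test sets keep the chance-AUC spread narrow), the network at a
  reduced NF = 8 / 2-epoch configuration per seed (a null task cannot
  leave chance regardless of training length; five full-scale trainings
  would add nothing but runtime). All AUCs stay within [0.4, 0.6] over
  five seeded cohorts.

## Known limitations

* The numpy network is CPU-only and unoptimized beyond BLAS-friendly
  memory layout; the full 128-filter/100-epoch configuration is buildable
  and trainable but meant for real hardware, not the test suite.
* The consistency selector's monotonicity makes the selection union
  inclusive; users wanting minimal subsets should use the CFS subset
  alone.
* The Hurst estimator is biased toward the center of [0, 1] at 56x56
  patch sizes; it is used as a relative roughness feature, not an
  absolute exponent estimate.
* VIA support covers polygon regions only (the format's other shapes have
  no meaning for this pipeline and raise a clear error).
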