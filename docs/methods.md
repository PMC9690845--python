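# Methods

## The segmentation model

The network is a fully convolutional encoder–decoder that maps a
single-channel image in [0, 1] to a per-pixel tumor probability. Two
encoders run in parallel on the same input.

**Basic encoder.** Five blocks; block *j* applies two 3×3 ReLU
convolutions with K_j kernels, K = (32, 64, 128, 256, 512), followed by
2×2 max pooling (stride 2) for j ≤ 4; block 5 is unpooled. Both
convolution outputs of each block are retained as skip sources.

**Row-column encoder.** Five blocks parallel to the basic blocks, each
with two branches. Branch 1 stacks two square ReLU convolutions
(A₁ = A₂ = 3 by default). Branch 2 applies an A₃×1 convolution, then a
1×A₃ convolution, then a square A₄ = 3 convolution; A₃ = (15, 13, 11, 9, 7)
per block. Both branches produce C_j = K_j channels and are merged by
element-wise addition, then fused by an A₅×A₅ ReLU convolution with
A₅ = (1, 5, 1, 1, 5); this fusion adds a third non-linearity to the main
path. Pooling mirrors the basic encoder. The 1-D pair gives a
cross-shaped receptive footprint — wide along rows and columns but not
diagonally — which matches horizontally layered breast anatomy and keeps
the effective receptive field small for small lesions; this is verified
in the tests by perturbation analysis in the linear regime.

**Decoder.** The two block-5 outputs (512 channels each at 1/16
resolution) are concatenated into a 1024-channel bottleneck. Each of four
up blocks upsamples 2× (a 2×2 stride-2 transposed convolution by default;
nearest-neighbor + 1×1 convolution as a config option), concatenates the
matching-level first-conv output of the basic encoder and the fused
output of the row-column encoder, applies an M₁ = 3 convolution to Y_j
channels, an M₂ channel-control convolution (M₂ = 1, 1, 1, 5), then
concatenates the basic encoder's second-conv output and closes with an
M₃ = 3 convolution; Y = (256, 128, 64, 32). A 1×1 convolution + sigmoid
produces the probability map. All convolutions are zero-padded "same",
so output shape equals input shape for any side divisible by 16. The
default model has 28 563 137 trainable parameters.

Choices the architecture description leaves open, resolved here and
configurable: the square-kernel sizes A₁, A₂, A₄ of the second encoder
(set to 3 — small squares are consistent with the design goal of a
compact receptive field); how the two bottleneck outputs jointly feed the
decoder (concatenation); the branch merge inside the dual-branch block
(element-wise sum, as the block equation's “+” reads); the pooling of the
second encoder (max, mirroring the first); padding (zero, "same");
weight initialization (seeded He-uniform); and no batch normalization.

A single-encoder ablation (`variant="basic"`: the basic encoder with the
same decoder, skips taken from it alone) is included as a comparison
baseline for the statistics tooling.

## Training

Soft Dice loss, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1 (per sample,
averaged over the batch), minimized with Adam. The published work fixes
only the loss; optimizer, learning rate, batch size and epochs are this
package's defaults (Adam, lr 10⁻⁴ for full-scale runs and 10⁻³ for the
CPU-sized width-reduced experiments, batch 8, 100 epochs) and are all
exposed in `TrainConfig`. No augmentation by default (flip/shift flags
exist but are off). Every fold of cross-validation reinitializes the
model from a fold-specific seed derived from the master seed; batching,
fold assignment and phantom generation draw from the same seed tree, so
single-threaded runs are bit-reproducible.

The network runs on a purpose-built numpy reverse-mode autodiff engine
(`estan._autodiff`): convolutions are computed by shift-and-gemm (one
matrix product per kernel tap), which keeps peak memory at one padded
input copy; float32 throughout, with float64 accumulation in the loss.
Gradient correctness is checked against central finite differences in
the tests.

## Evaluation metrics

With TP, FP, FN pixel counts against a nonempty ground truth G:

* TPR = TP/|G|; **FPR = FP/|G|** (not FP/negatives — with the huge
  background of BUS images the conventional FPR is uninformative; this
  ratio exceeds 1 when the false region outgrows the tumor);
* JI = TP/(TP+FP+FN), DSC = 2TP/(2TP+FP+FN) = 2·JI/(1+JI);
* AER = (FP+FN)/|G| = FPR + (1 − TPR);
* HD = exact bidirectional Hausdorff distance and MAE = average symmetric
  boundary distance, both between the 4-connected boundary pixel sets
  (border pixels count as boundary), in pixels, computed from exact
  Euclidean distance transforms. An averaged-Hausdorff variant and an
  area reading of "MAE" exist in the literature; the exact max-max-min
  Hausdorff and the boundary MAE are used here.

Probability maps binarize at 0.5 (configurable). An empty prediction
yields (TPR 0, FPR 0, JI 0, DSC 0, AER 1) and flags HD/MAE as undefined;
flagged samples are excluded from HD/MAE averages and the exclusion
count is reported alongside every table. Samples with empty ground-truth
masks are excluded from metric computation altogether.

Metrics are computed at the 256×256 working resolution by default
(the evaluation resolution is a package choice; callers can evaluate at
original resolution by passing un-resized masks). Tumor size, by
contrast, is always measured on the original-resolution mask: the
longest axis is the Feret diameter — the maximum pairwise distance
between foreground pixel centres, computed on the convex hull and tested
against the all-pairs oracle. The fitted-ellipse major axis is a
plausible alternative reading of "longest axis"; the Feret diameter was
chosen as the literal one. Masks with several components use the global
maximum. Size groups are half-open above — (0,100], (100,120],
(120,160], (160,∞) — and *small* means axis ≤ 120 px; this inclusivity
makes the two small groups' union equal the small-tumor set (a 19-image
and a 30-image group combine to 49, matching the published per-dataset
accounting).

## Significance testing

Per-image metric values (not per-fold means) of two methods are compared
with the two-sided Wilcoxon signed-rank test: zero differences discarded
(classic handling, not Pratt), midranks for ties, exact enumeration of
all 2ⁿ sign assignments for n ≤ 12, and a normal approximation with tie
and continuity corrections beyond. The exact crossover at 12 keeps
enumeration ≤ 4096 terms. Family-wise error across the metric family is
controlled by Holm–Bonferroni (delegated to statsmodels) at α = 0.05.

## The phantom generator

Each phantom emulates the gross structure of a B-mode breast image on a
500×500 default grid (so tumor axis lengths land directly in the size
groups above):

* **Anatomy**: four horizontal bands, top→bottom skin / premammary fat /
  mammary / retromammary, with default height fractions
  0.08/0.17/0.45/0.30 and mean echogenicities 0.75/0.35/0.55/0.25 —
  a bright thin skin line, dark fat, mid-grey mammary tissue.
* **Tumor**: a rotated ellipse centred in the mammary band (kept wholly
  inside the band whenever it fits), aspect ratio minor/major in (0, 1],
  radius modulated by a random harmonic series of orders 2–5 whose peak
  relative amplitude is `boundary_irregularity` (≤ 0.5); intensity inside
  drops by `tumor_contrast`. The rasterized mask's Feret diameter is
  calibrated to the requested axis length by up to four rescale
  iterations, and the realized length stays within 10% of the request
  (verified over 100 random geometries).
* **Posterior shadow** (off by default): column-wise attenuation below
  the tumor, 1 − s·(1 − e^(−depth/τ)) with τ = height/10.
* **Speckle**: a unit-mean gamma field (shape 4 by default), Gaussian
  smoothed (σ 1.5 px), renormalized to mean 1 and multiplied into the
  clean template — the standard multiplicative proxy for ultrasound
  speckle. Setting the shape to infinity disables it exactly, leaving
  the clean band+tumor template.

Dataset generation draws axis lengths from a right-skewed log-normal
(mode 130 px at the 500-px reference, σ = 0.45, clipped to [30, 320] px,
scaled proportionally for other image sizes), mirroring the strong
positive skewness of clinical BUS size distributions in which most
tumors fall below 150 px; aspect, orientation (±30° about horizontal,
keeping the major axis roughly along the tissue layering),
irregularity and contrast are drawn per sample from realistic ranges.
Per-sample seeds derive from the master seed.

The phantom reproduces layered anatomy, hypoechoic contrast and
multiplicative noise — the structural priors the row-column encoder is
built around — but none of the acoustic physics (refraction,
reverberation, real lesion texture, device post-processing) and no
benign/malignant appearance differences. Passing tests on phantoms
therefore demonstrate that the implementation learns and evaluates
correctly, not that the architecture attains any particular clinical
performance; the published clinical benchmarks require the three
external BUS datasets and GPU-scale training and are out of scope here.

## Problem sizes and degenerate inputs

The test suite and the acceptance script run CPU-sized configurations,
chosen as the smallest sizes that still exercise every code path: the
full-width model is built and audited and runs one 256×256 forward pass;
learning checks use a channels÷4 model on 64-px phantoms (8-sample
overfit to training DSC > 0.9 with early stopping within 200 epochs;
20-sample 2-fold cross-validation at 30 epochs); oracle checks use
16×16–64×64 masks in the thousands. Degenerate inputs are contracts,
not surprises: empty masks raise (or are flagged and excluded where the
pipeline must continue), a single-pixel mask has Feret diameter 0,
pooling rejects odd spatial sizes, the model rejects input sides not
divisible by 16, and all-zero differences make the signed-rank test
raise rather than emit p = 1.

## Known limitations

* The numpy engine is single-threaded-deterministic but slow at full
  width; the published clinical setup (256×256, full channels, hundreds
  of epochs, five folds) is out of CPU reach — the architecture is
  audited at full width, trained at reduced width.
* Phantom realism is a stand-in: no speckle statistics or tumor-shape
  distributions from real data were fitted.
* Evaluation at original resolution is supported but not the default;
  published evaluation resolution is unstated.
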