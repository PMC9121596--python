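# Methods

## Problem and scope

Differential counting of white blood cells (WBC) — neutrophils,
eosinophils, basophils, lymphocytes, monocytes — from stained blood-smear
images is a five-class image classification task with strong class
imbalance (basophils are rare) and high between-class visual similarity.
`wbcnet` implements a compact, fully specified pipeline for this task:
a shallow CNN classifier (W-Net), its SVM-head variant, an LSTM baseline,
stratified cross-validated evaluation, transfer-learning fine-tuning, a
per-class DCGAN image synthesizer, and a suite of generated-image quality
checks.  A procedural synthetic-cell generator stands in for clinical data
so every stage is exercisable and testable offline.

All neural-network machinery is implemented in NumPy (`wbcnet.nnops`) with
hand-written backward passes; convolutions are expressed as one BLAS matmul
per kernel tap.  This keeps the package runnable on a plain scientific
Python stack with no deep-learning framework, at the cost of GPU support,
which the desk-scale experiments here do not need.

## Preprocessing

Raw device images are 361 (H) x 360 (W) x 3 RGB.  Three steps, in order:

1. **Border crop** — remove top 80, bottom 81, left 80, right 80 pixels,
   leaving 200 x 200 x 3.  Pure sub-array extraction; row 0 is the image
   top, extents are half-open index ranges.  The asymmetric 80/81 vertical
   margins are only consistent with height 361, which fixes the
   width-x-height reading of the device size.
2. **Bilinear resize** to 128 x 128 x 3, align-corners-false convention:
   output pixel i samples source coordinate (i + 0.5)·in/out − 0.5, clipped
   to the valid range.  Per-channel values stay within input bounds.
3. **Normalization** to [0, 1] by per-image global min–max,
   out = (in − min)/(max − min); a constant image maps to zeros.  The
   normalization formula is a design choice (the alternatives
   `minmax_channel` and fixed `scale255` are selectable); global min–max is
   scale-free and guards against numeric over/underflow.

## W-Net

Input 128 x 128 x 3.  Three blocks of {3x3 conv, stride 1, same padding;
ReLU; 2x2 max-pool, stride 2, valid; dropout p = 0.6} with 16, 32, 64
filters, then flatten (16 x 16 x 64 = 16,384), dense 1024 + ReLU + dropout,
dense 5.  Same padding and conv biases are load-bearing inferences: they
are the only combination reproducing both the published per-block feature
counts (65,536 / 32,768 / 16,384) and the exact trainable-parameter total

    448 + 4,640 + 18,496 + 16,778,240 + 5,125 = 16,806,949.

Weights are Xavier-uniform, W ~ U[−x, x] with x = sqrt(6/(fan_in +
fan_out)); conv fans are kh·kw·c_in and kh·kw·c_out (Glorot's convention);
biases start at zero.  Dropout sits after each pooling layer; placement
does not affect the parameter count.

Two heads share this architecture and parameter count and differ only in
training loss and output mapping: the softmax head trains with
max-shift-stabilized softmax cross-entropy −log q(true); the SVM head
trains with a one-vs-all multiclass hinge, summing max(0, 1 − t·y) over
the five raw scores with t = +1 for the true class and −1 otherwise
(the minimal multiclass extension of the binary hinge).

The LSTM baseline consumes each image as 128 timesteps (rows) of 384
features (128 columns x 3 channels, channel-fastest within a row — an
arbitrary but documented flattening order), through one 32-unit LSTM
(4·((384 + 32 + 1)·32) = 53,376 parameters) and a 5-way softmax head.

## Training

Adam at learning rate 1e-4, batch size 5, 500 epochs by default; β1 = 0.9,
β2 = 0.999, ε = 1e-8 (standard defaults, surfaced in config).  The update
is Δθ = −η·m̂/sqrt(v̂ + ε) with the epsilon inside the square root, as the
method was specified; at ε = 1e-8 the difference from the common
m̂/(sqrt(v̂)+ε) form is far below training noise.  Each epoch visits a
seeded uniform permutation; the short final batch is kept, so the actual
step count is epochs·ceil(n/batch) while the conventionally quoted figure
n·epochs/batch (`equivalent_iterations`) assumes exact division.  Small
batches are deliberate for imbalanced data: one misclassified rare-class
sample carries 20% of a 5-sample batch mean.  No augmentation, no early
stopping.  Fine-tuning loads a checkpoint (validated by an
architecture-spec hash) and continues with all layers trainable.

Training is bit-reproducible given seed, data order and BLAS build; a
different BLAS vendor/threading configuration may round differently.

## Evaluation

Stratified k-fold (default k = 10): within each class, indices are
shuffled by the seed and dealt round-robin, so per-class fold sizes differ
by at most one and each record is tested exactly once.  All metrics derive
from the 5x5 confusion matrix (rows true, columns predicted): accuracy =
trace/total; per-class precision/recall are column-/row-normalized
diagonals; F1 is their harmonic mean; macro averages are unweighted
(weighted versions are also emitted).  Zero-denominator cells yield 0 with
a warning flag rather than NaN.  The per-class "accuracy" figure quoted in
this field is per-class recall and is exposed under that name.  One-vs-rest
ROC curves group tied scores and integrate by trapezoid (equivalently the
Mann–Whitney U statistic); PR AUC is step-interpolated average precision,
avoiding the trapezoid's optimistic bias.  A class with one-class truth
gets NaN AUCs flagged `undefined`, never a fabricated value.

## DCGAN

One generator/discriminator pair per class, trained on that class's
preprocessed [0, 1] images with the minimax value function
E[log D(x)] + E[log(1 − D(G(z)))], z ~ N(0, I), latent dimension 100.
D maximizes both terms (one real + one fake batch per step at batch size
1, matching the two expectation terms); G minimizes log(1 − D(G(z))) by
default, with the non-saturating −log D(G(z)) variant behind a flag.

Layer inventory (six convolutional layers plus one dense in each network)
is fixed; widths and kernels are design choices: D uses stride-2 3x3 convs
32-64-128-256-512-512 (spatial 128 -> 2) with LeakyReLU(0.2) and dropout,
then dense 2048 -> 1 and sigmoid; G maps the latent through a dense layer
to 4x4x512, five stride-2 4x4 transposed convs 512-256-128-64-32 (spatial
4 -> 128) with batch norm + ReLU + dropout, and a stride-1 transposed conv
to 3 channels under a final sigmoid, so outputs are in [0, 1] for any
weights.  Batch norm lives in G only and uses running statistics at
sampling time.  Stated hyperparameters: SGD with momentum 0.9 ("momentum"
is read as the optimizer's coefficient, the more natural reading; an Adam
option exists for practical use), learning rate 1e-5, dropout 0.6, batch
size 1, 10,000 epochs.  A `GanConfig.debug()` scale (32 x 32, narrow
widths, Adam, non-saturating loss) mirrors the architecture for tests.

## Generated-image validation

Four checks: (1) classify generated images with a trained classifier;
(2) train a fresh classifier on generated images only and evaluate on real
only; (3) the cosine-similarity gap — per class, the mean cosine over the
full originals-vs-originals comparison (n x n, self-pairs included; their
contribution is O(1/n)) minus the mean over all original x generated
pairs, reported as an absolute difference in percentage points.  Including
the diagonal makes identical sets give a gap of exactly 0, which anchors
the statistic's degenerate case; both means are seeded-subsampled above a
1e5-pair budget.  Images are flattened row-major channel-last; cosine is
invariant to one global rescaling of all images but not to per-image
normalization, so the normalization state is recorded in the report.
(4) Blinded-rater scoring: confusion matrix, accuracy and a per-source
(original vs generated) error breakdown of an expert's answer sheet.

## Synthetic fixture generator

`synthetic_cells` renders one centered cell per image at 361 x 360 x 3 on
a pale smear background from simple geometry: cytoplasm ellipse, nucleus
ellipses, granule disks, plus Gaussian sensor noise.  Morphology follows
each type's textbook Wright–Giemsa appearance — neutrophil: 3–5 small
violet lobes, pale lilac cytoplasm; eosinophil: 2 lobes with dense bright
orange-red granules over orange-pink cytoplasm; basophil: dark purple
granules obscuring the nucleus; lymphocyte: one large round dark nucleus
with a thin blue rim; monocyte: largest cell, kidney-shaped indented
nucleus, gray cytoplasm.  The default class mix is the imbalanced
30/20/6/26/18% distribution.  Colors and geometry were chosen once for
class distinctness (a nearest-centroid rule on mean RGB separates a
250-image set at ~100%) and are not meant to be photorealistic: no
red-cell background, no staining variability, no focus/illumination
artifacts, no touching cells.  A green test on these fixtures therefore
establishes that the pipeline's mechanics learn and evaluate correctly on
separable data — not clinical-grade performance.

Determinism: `render_cell` is a pure function of (class, seed, size);
record i of class c draws its seed from
`SeedSequence([master_seed, class_index, i])`, so any record can be
re-rendered in isolation.  The CLI fans one global seed out to per-module
seeds via sha256("<seed>:<module>") mod 2^31.

## Numerical choices and degenerate inputs

* Softmax cross-entropy uses a max shift; probabilities are clipped at
  1e-30 before the log.  GAN probabilities are clamped 1e-7 from {0, 1}.
* Max-pool ties take the first maximum (gradient flows to one element).
* All-zero confusion matrices, empty datasets, zero vectors in cosine
  similarity, classes below k in stratification, and checkpoint/spec
  mismatches raise explicit errors rather than propagating NaNs.
* Model arithmetic runs in float32; losses and metrics accumulate in
  float64.

## Known limitations

* CPU-only and desk-scale: the published protocols (500-epoch training on
  6,562 images, 10,000-epoch GAN runs) are supported in configuration but
  take hours; tests and the acceptance script run minutes-scale reductions
  and say so.
* The fixture generator's separability means results on it upper-bound
  nothing about clinical data.
* The LSTM baseline supports full BPTT training but is tuned for nothing;
  it exists as an architectural comparison point.
* AlexNet/VGG/ResNet comparison variants are out of scope; their published
  parameter counts are not reconstructible from layer inventories alone.
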