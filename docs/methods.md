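# Methods

## Scope and design

`stripeid` implements the identification stage of a two-stage striped-animal
re-identification pipeline. The part detector is deliberately out of scope:
the package consumes COCO-format boxes from any detector and begins at
cropping. (For the record, the detector configuration this pipeline is
normally paired with is YOLOv5 trained for 300 epochs with SGD, batch 16,
initial learning rate 0.01 under a cosine schedule.)

Because no deep-learning framework is assumed, the network is built on
numpy in two strictly separated layers:

* **`graph`** — a declarative, ordered set of layer specifications. Shape
  inference and parameter counting are closed-form functions of the specs,
  so structural claims (output shapes, parameter totals) never depend on
  instantiating weights.
* **`ops`** — a minimal reverse-mode autodiff engine (NHWC, float32) that
  interprets the same specs for forward and backward passes. Convolution
  is computed as a sum of k² shifted matrix products; gradients of every
  op are tested against central finite differences, and forwards against
  independent sliding-window transcriptions.

One executor serving both counting and training means the counted model
and the trained model cannot drift apart.

## Architecture dialects

Published descriptions of InceptionResNetV2 disagree on block repetition:
the narrative schema is 5× A, 10× B, 5× C, while the widely distributed
reference implementation uses 10× A, 20× B, 10× C with residual scales
0.17/0.10/0.20 and a final 1×1 convolution to 1536 channels. Only the
reference dialect has a bit-exact anchor — a printed parameter total of
54,336,736 — so it is the default; the `original` dialect (5/10/5, no
final projection, 2080-channel output) is selectable for comparison. The
residual scaled-add + ReLU is applied uniformly to every block, including
the last C block (some implementations special-case it with scale 1 and no
activation; the parameter count is unaffected).

The multi-branch base stage between the stem (192 channels) and the A
blocks (320 channels) is part of `build_backbone`: the A blocks' residual
projection width and the parameter total both require it.

### Batch normalization and parameter accounting

Batch normalization is **scale-free**: y = (x − μ)/σ + β, with ε = 10⁻³.
Each normalized channel therefore carries 3 numbers — one learnable shift
plus running mean and variance. This is the only convention under which
the reference backbone counts exactly 54,336,736 (convolution weights
54,200,160 + residual-projection biases 45,760 + 3 × 30,272 batch-norm
channels); adding a learnable scale would overshoot by 30,272. The total
deliberately includes running statistics, matching how framework model
summaries report "params".

Weights initialize from a seeded truncated normal (±2σ redraw) with He
scaling √(2/fan-in); shifts and biases start at zero. The seed lives in
`ArchConfig`, making any forward pass reproducible bit for bit.

### Attention

CBAM's internal hyperparameters are pinned by parameter accounting: over
the grid r ∈ {2,4,8,16} × bias on/off × spatial kernel ∈ {3,7}, only
(r = 8, bias-free, 7×7) reaches the printed 589,922 at 1536 channels
(2·1536·192 = 589,824 MLP weights + 7·7·2 = 98 spatial weights). The
channel gate is applied first and the spatial gate second (sequential
gating, as in the original CBAM design); a notation that composes both
before multiplying once is treated as shorthand for this. SE is the
channel gate without the max-pool path; ECA replaces the MLP with a
bias-free local 1-D convolution across channels (kernel 3 by default).
The gate attaches after the backbone's final 1536-channel map.

## Training contract

Cross-entropy on softmax logits, Adam (default, lr 0.001, β = 0.9/0.999)
or SGD, batch 16, 20 epochs; the test split is evaluated after every epoch
so the maximum and fifth-highest Top-1 statistics can be read off the log.
Dropout (default 0.4; the sweep grid {0, 0.1, …, 0.5} is exported) uses
inverted scaling, so rate 0 makes train- and eval-mode forwards literally
identical. Learning rate 0 is permitted as a frozen-model control.

Mode switching: dropout is the only layer that consults the training flag
beyond batch normalization's standard two-phase statistics (batch moments
while training, running averages at inference). `forward` exposes the BN
momentum (default 0.9); with momentum 0 the running state equals the last
batch's moments, which is how the "train = eval at dropout 0" property is
verified exactly. Evaluation-mode forwards are idempotent and
deterministic. Argmax ties resolve to the lowest class index.

`load_pretrained` replaces backbone tensors only (attention and head stay
at initialization), staging all arrays before committing so a shape
mismatch — reported per layer — leaves the model untouched.

## Preprocessing and augmentation

Crops are padded to a square along the long side with black fill and
centered content (black is the least-information fill and keeps the pixel
sum invariant), bilinearly resized to the input size, and mapped to
x/127.5 − 1. The 7-variant photometric expansion is brightness ×0.7/×1.3,
contrast ×0.7/×1.3 (about the grayscale mean), hue +0.05 of the hue
circle, saturation ×1.3, and Gaussian blur σ = 1 — magnitudes are package
defaults, chosen as visually moderate, and fully configurable. Identity
magnitudes return the input byte-for-byte.

Splitting shuffles with a seed and gives every part after the first
⌊n·r/Σr⌋ items, the first part absorbing the remainder (10 → 8/1/1 at
8:1:1, 10 → 8/2 at 4:1, 241 → 193/24/24). Augmentation after splitting is
the default in the CLI workflow so that copies of one photograph cannot
straddle the train/test boundary.

## Detection scoring

IoU is standard intersection-over-union in COCO pixel convention. AP per
class uses greedy matching by descending score (ties by input order; each
ground truth matched at most once, best IoU winning) and all-point
interpolation — the area under the monotone precision envelope — summed
over recall increments; mAP averages over classes present in the ground
truth. The confusion matrix is matched class-agnostically, has a
background row (unmatched predictions) and column (missed ground truths),
and is row-normalized over true classes. These conventions are the
package's own choices where the usual presentations leave them open.

## Synthetic data

The generator emulates the structure of a real part-image dataset: a
population of individuals, each defined by 3–5 oriented sinusoidal band
systems (frequencies 4–9 cycles per body, orientations 60–120°, random
phases). The summed field thresholded at −0.25 gives tiger-like dark bands
on an orange elliptical body over a smooth textured background. The right
flank is the mirrored left flank; the face is the same pattern at double
frequency inside a smaller circular mask. Nuisance per image: brightness
×(1 ± 0.15), Gaussian blur σ ∈ [0, 0.8], placement jitter ±3 px, sensor
noise σ = 4 gray levels. Each record's nuisance stream is seeded by
`SeedSequence([master_seed, record_index])`; with all nuisance ranges at
zero, rendering is a pure function of (individual, part).

Defaults (12 individuals × 3 parts × 10 images at 96 px) were chosen so a
1-nearest-neighbor pixel baseline clearly beats chance while the full
train/eval loop stays in the tens of seconds on one CPU core. What passing
tests show is that the architecture, gradients, and training loop work and
that the pipeline can extract a pose-stable texture identity; they do not
show robustness to viewpoint, occlusion, lighting extremes, background
clutter, or the long-tailed identity distributions of real camera-trap
data — no claim about real-world accuracy follows from the synthetic
results.

## Desk-scale configuration

`ArchConfig.tiny` keeps the full topology (stem, base, A/RA/B/RB/C,
attention, head) at 1/8 channel width with one block of each type and a
96 px input; channel widths round to max(1, round(m·C)) so branch
concatenation stays well defined at any multiplier. The acceptance script
trains this variant for 20 epochs on the default synthetic population
(problem sizes: 288 training and 72 test images) — small enough to run
alongside the structural checks in under a minute — and reaches 100%
training accuracy with held-out accuracy around 80–90% depending on seed.

## Known limitations

* Single-threaded numpy execution: the reference-width model is buildable
  and countable instantly, but training it at 299 px is impractical here;
  training claims are desk-scale by design.
* No learning-rate schedule, weight decay, or label smoothing — the
  training contract is deliberately the plain one stated above.
* The COCO reader supports the subset of the schema needed for boxes
  (images / annotations / categories); segmentation masks and crowd flags
  are ignored.
* `avgpool` (base stage) includes zero padding in its mean, a simplicity
  choice that differs from implementations that renormalize at borders;
  at interior pixels the two agree.
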