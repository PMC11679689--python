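# Methods

## Problem and model

Skeletal maturity on hand–wrist radiographs can be graded from the distal
radius and ulna (DRU scheme): the radiolucent growth plate (physis) between
the bone shaft and its epiphysis narrows with age, the epiphysis develops a
medial "cap" over the metaphysis around the pubertal growth peak, and the
plate finally fuses at skeletal maturity. `drumtl` grades a single-bone ROI
crop into one of seven ordinal stages (radius R5–R11 or ulna U3–U9; the
two bones use separate model instances of identical architecture) while
jointly segmenting the bone, on the hypothesis that boundary morphology
carries the stage signal.

The architecture is a multi-task network with a hard-shared encoder:

* **Backbone** — an attention-gated U-Net with `levels` = 5 (four encoder
  blocks + bridge). Each block is two 3×3 convolutions, each followed by
  (toggleable) batch normalisation and ReLU; 2×2 max pooling halves the
  resolution between encoder blocks and channel width doubles from
  `base_channels` (default 32 → 32, 64, 128, 256, bridge 512). The decoder
  mirrors the encoder with bilinear upsampling + 3×3 channel-reducing
  convolution, concatenation with the (gated) skip, and a refinement block;
  a final 1×1 convolution + sigmoid yields the segmentation probability
  map at input resolution.
* **Attention gate** — for skip feature `x^l` (F_l channels) and coarser
  gating signal `g` (the bridge for the deepest skip, otherwise the
  preceding decoder block):

      q = ψ( σ₁(W_x·down(x) + W_g·g + b) ) + b_ψ
      α = up( σ₂(q) ),   x_att = α ⊙ x

  with σ₁ = ReLU, σ₂ = sigmoid, all projections 1×1 convolutions,
  intermediate width F_int = max(1, F_l/2). `down` is block-mean (area)
  pooling of `x` to `g`'s resolution and `up` a half-pixel-centre bilinear
  upsample of α back to `x`'s resolution. With `use_attention=False` the
  identical architecture without gates is the conventional-U-Net ablation;
  the two share every non-gate parameter shape.
* **Grading head** — global average pooling of three taps (last encoder
  block, bridge, first decoder block), concatenated (e.g. 256+512+256 =
  1024 features at base 32), then dense 256 → ReLU → dropout → dense 128 →
  ReLU → dropout → dense 7 + softmax. The regression variant replaces the
  last layer by a single ReLU unit; its output is rounded half-up and
  clipped to [0, 6] at decode time. One backbone pass feeds both branches.

## Losses

* Segmentation: smoothed soft Dice loss
  `L_seg = 1 − (2·Σ p⊙t + θ)/(Σp + Σt + θ)` computed on probabilities
  per image and averaged over the batch; θ defaults to 1.0.
* Classification: mean cross-entropy against one-hot stages. The public
  `cross_entropy_loss` operates on row-stochastic probabilities (clamping
  at 1e-12 inside the log, with a warning); the training loop evaluates the
  identical quantity through a log-softmax of the head logits, which keeps
  gradients finite when float32 softmax underflows. The regression head is
  trained with mean squared error on the integer stage index.
* Combined objective: `L_m = λ·L_seg + (1−λ)·L_cla`, λ ∈ [0, 1], default
  λ = 0.4. At λ = 1 the head parameters receive exactly zero gradient and
  grading stays at chance; at λ = 0 every parameter unreachable from the
  classification taps (the output projection and all decoder machinery
  beyond the first decoder block — the first block feeds the GAP tap) is
  provably untouched. Both boundary behaviours are asserted in the suite.

## Training protocol

Two phases. (1) The backbone alone is pretrained on a segmentation-only
pool split 7:1:2 (seeded shuffle; floor allocation, remainder to train)
with Dice loss, model selection on validation loss, IoU/DSC reported on
the held-out share. (2) The multi-task model is built fresh, its encoder
*and bridge* initialised bit-exactly from the pretrained backbone
(encoder-only transfer available by flag), and trained under `L_m` with
five-fold stratified cross-validation. Training folds are doubled
deterministically (original + horizontal mirror, image and mask flipped
together); validation folds are never augmented. Optimisation is Adam,
batch 16, initial learning rate 0.005 with a ×0.5 step decay every 10
epochs, early stopping on validation `L_m` (patience 10). After CV the
final model is refit on all folds (fold-ensemble available by flag). A
`run_cv=False` fast path trains a single stratified ~10 % holdout instead
of the full CV loop; scaled-down experiments use it. An SHA-256 hash of
the shared-trunk weights is recorded before the first gradient step so
transfer-then-train ordering is auditable. One master seed fans out into
split/init/shuffle streams, so every run is bit-reproducible.

Ablation variants toggle exactly one ingredient: `unet_backbone` (no
gates), `no_pretrain` (random encoder init), `regression_head` (single
ReLU output), and `two_stage` (the pretrained backbone segments, the image
is hard-masked by the predicted mask, and a separately trained
classification-only model of the same architecture grades the masked
image; segmentation metrics are credited to the first stage).

## Evaluation

Hard masks are probabilities thresholded at 0.5. IoU = |X∩Y|/|X∪Y| and
DSC = 2|X∩Y|/(|X|+|Y|); when both masks are empty both metrics are 1.0,
when exactly one is empty both are 0.0. Classification reports accuracy,
per-stage precision/recall/F1 and their macro averages over the stages
present in the truth (undefined ratios count as 0 with a warning), and a
7×7 confusion matrix (true rows × predicted columns). 95 % confidence
intervals are percentile bootstrap over test samples (default 5000
resamples, seed-deterministic; undefined resamples are redrawn and
counted). When several repeated trainings are evaluated the point estimate
is the mean over repeats and the bootstrap pools the repeats' prediction
sets; the pooled confusion matrix then has row sums of repeats × the
per-class counts.

## Synthetic data generator

The generator renders a stylised long-bone end on a square canvas:
a vertical shaft, an elliptical epiphysis above it, and a stage-dependent
physis. The schedule (in 64-px canvas units) makes the physis gap strictly
decreasing over stages 0–6 (12 → 1.2 px), grows the epiphysis, raises a
medial capping lip through the mid stages, adds a styloid-like bump at
stages 2–4, and bridges the gap at stages 5–6 (fusion fraction 0.5 → 1.0).
Geometry is jittered by a bounded, seeded amount; the mask is the exact
pre-noise foreground; intensities get a brighter cortical rim, a mild
vertical gradient, Gaussian blur (σ = 0.7 at 64 px) and Gaussian noise
(sd = 0.05), clipped to [0, 1]. A nearest-centroid probe on gap/fusion/area
features extracted from the masks reaches > 0.9 over 700 samples, so the
stage signal demonstrably lives in the boundary — the structural
assumption the multi-task model exploits.

What the generator does **not** emulate: radiographic texture (trabecular
pattern, soft tissue, exposure variation), anatomical shape variability,
label noise between adjacent stages, and the class imbalance of clinical
cohorts. Passing tests therefore demonstrate that the implementation
learns boundary-borne stage signal end to end, not that the reported
clinical accuracy transfers.

## Numerical and scale choices

* The tensor layer is a purpose-built NumPy reverse-mode autodiff:
  convolutions run as channels-last im2col + BLAS GEMM (the input gradient
  of a stride-1 convolution is again a convolution with the flipped,
  channel-transposed kernel), resampling as separable interpolation
  matrices whose adjoints are transposes. Training uses float32;
  gradient-correctness checks build float64 models and agree with central
  finite differences to 1e-4 relative.
* Default test/experiment resolution is 64×64 (networks are parametric in
  `side`; 256 is the intended full-scale setting). The scaled-down study
  used by the acceptance script and the heavy tests is: 100/70/20 samples
  per stage (pretrain/multitask/test) at 64×64 with base 16 channels,
  2 pretraining epochs with 4 (test suite) or 6 (acceptance script)
  multi-task epochs; the ablation comparison runs
  16/12/8 per stage at 32×32 with base 8, 10 + 14 epochs, averaged over
  three seeds — sizes at which each variant trains to its ceiling on the
  synthetic task.
* Ties in the softmax argmax resolve to the lowest stage; regression
  decoding is round-half-up then clip. Checkpoints are `.npz` archives
  embedding a version tag and the backbone configuration.

## Known limitations

* The synthetic task is nearly separable, so ablation differences are
  compressed relative to the clinical dataset; orderings are asserted with
  small tolerances rather than effect sizes.
* Batch-norm running statistics are transferred together with trunk
  weights; with very small pretraining pools (tens of images) transfer can
  be counterproductive — pool sizes in the shipped experiments are chosen
  large enough that pretraining helps or is neutral.
* No GPU path; wall-clock scales linearly with pixels × channels², which
  is why full-scale 256×256 training is out of scope for the routine
  suite.
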