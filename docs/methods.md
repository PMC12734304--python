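# Methods

## Problem setting

`voxslim` implements a lightweight 3D convolutional classifier for
single-channel volumetric MRI (binary classification, e.g. disease vs.
control in dementia staging), together with the machinery that makes such a
network small: depthwise-separable convolutions, a multi-scale fusion block,
a parameter-free attention, BatchNorm-γ channel pruning, and a complexity
profiler that quantifies what was gained.  Because the clinical MRI
collections this family of models is trained on are access-controlled, the
package ships a synthetic phantom generator so that every stage — training,
pruning, evaluation, interpretability — is exercisable end to end without a
download.

## Network

The classifier is a chain over feature maps of shape `(C, D, H, W)`:

* **Stem**: a 1×1×1 convolution mapping the single input channel to 24
  channels, then BatchNorm and ReLU.
* **Stages**: one depthwise-separable unit per stage width — a depthwise
  3×3×3 convolution (one kernel per channel, zero padding), BN, ReLU, then a
  1×1×1 pointwise convolution mixing channels, BN, ReLU.  Non-dilated stages
  downsample with stride-2 depthwise convolutions; the final stages use
  dilated depthwise kernels (rates 2 and 4 by default) at stride 1, widening
  the receptive field at no parameter cost.
* **LMF block** (one stage): parallel depthwise-separable branches at kernel
  scales 3³ and 5³ with same-padding so they align; the channel-concatenation
  of the branch outputs is globally average-pooled into a descriptor `z` of
  length S·C, passed through two small linear layers with ReLU, and a softmax
  yields per-scale weights α (Σα=1, α>0); the output is the convex fusion
  Σ αᵢ Fᵢ.
* **ILS attention** (parameter-free): per sample and channel, with spatial
  mean μ and population variance φ²,
  `x̂ = (x − μ)/(φ² + λ)·0.5 + 0.5`, mask `M = sigmoid(x̂)`, output `X ⊙ M`.
  λ = 1e-4 guards zero variance, where x̂ collapses to 0.5 and the mask to
  sigmoid(0.5) ≈ 0.622.  We read φ² as the variance (the only dimensionally
  coherent reading; the sigmoid is the separate σ(·)); the same worked
  numbers fall out: for a two-voxel channel {0, 1}, x̂(1) = 1.4996 and
  Y(1) = 0.81756.
* **Head**: global average pooling and a linear layer to the class scores.

Biases are disabled on all convolutions (each is followed by BN).  All
randomness in initialisation flows from one seed, so instantiation is
deterministic.

### Width calibration

The architecture's published description fixes the stem at 24 channels, the
kernel set {3, 5} and dilation on the last stages, but not the stage count or
widths.  We use five stages on a 24/64/128/256/512 ladder and calibrate a
single width multiplier by grid search
(`voxslim.complexity.calibrate_width_multiplier`, step 0.05 over [0.5, 3])
against the published unpruned budget of 0.92 M parameters.  The selected
multiplier 1.95 gives default widths (24, 125, 250, 499, 998) and 918,055
parameters (−0.2%).  This is a calibrated reconstruction, not a ground-truth
architecture; everything downstream (pruning budgets, profiler) treats it as
such.

## Pruning

Network-slimming-style structured pruning driven by the BatchNorm scale γ
that follows each stage's pointwise convolution:

* **Sparsity**: the training loss adds λ·Σ|γ| (λ = 1e-4) over prunable BNs,
  pushing unimportant channels toward zero.
* **Threshold**: every 5 epochs, the nearest-rank **lower** quantile τ of the
  pooled |γ| over all surviving unprotected channels is computed at
  r = 0.05 of the remaining channels (global pooling across layers — the
  network-slimming convention; a per-layer mode exists behind a flag).
  Channels with |γ| **strictly** below τ are pruned; ties at τ are kept, so
  r = 0 and all-equal pools prune nothing.
* **Masking**: pruning a stage-output channel zeroes its pointwise row and
  BN γ/β, and in the consumer block the matching depthwise kernel, depthwise
  BN entries, and pointwise column.  This makes the masked forward pass
  *exactly* the forward pass of the physically compacted model — the central
  correctness oracle, tested on randomized architectures.  Masks are
  monotone (a pruned channel never returns) and are re-applied after every
  optimiser step so gradients cannot resurrect dead channels.  Every layer
  keeps at least one channel.
* **Stopping**: a fixed per-step ratio compounds — 5% every 5 epochs over
  100 epochs would remove far more than the published pruned budget — so the
  schedule carries an explicit parameter-reduction target (default 0.47,
  calibrated to the published 0.92 M → 0.49 M transition).  Within a step,
  candidates are masked in increasing |γ| order and the step stops as soon
  as the masked-equivalent parameter count reaches the target, landing on
  the budget instead of overshooting by a whole step.
* **Protected**: stem, classifier head, LMF gate, and the LMF fused output
  channels.  The fused output channel is tied across both branches and feeds
  the gate input, so no single γ ranks it; protecting it keeps the
  masked ≡ compacted equivalence exact.  The LMF *input* follows its
  upstream stage's mask (branch kernels and gate input columns are sliced).

`compact` physically removes masked channels, slicing depthwise kernels, BN
parameters and running statistics, pointwise rows/columns, LMF branch inputs,
and head columns; outputs agree with the masked model to float round-off.

## Complexity profiler

* **Parameters**: direct enumeration of trainable entries (kernels, linear
  weights, biases, BN γ/β).  The published per-layer formula is printed with
  two kernel factors; we count the full 3D kernel volume (k³), the only
  reading consistent with the FLOPs formula and the 3D setting.
* **FLOPs**: 2 ops per multiply-add over convolutions and fully connected
  layers: `2·D·H·W·(C_in/groups)·K³·C_out` per conv at its actual output
  size (dilation changes nothing), `2·m·n` per linear layer.  BN,
  activations, pooling, the ILS elementwise work, and the LMF gate's two
  small linear layers are excluded, and this scope is the documented contract
  for reconciling with other profilers.
* **Model size**: `Para × b` bytes (b = 4 for float32), also in MiB
  (bytes/2²⁰) — the convention consistent with the published size column.
* **Performance density**: accuracy (percent) per million parameters,
  `PD = ACC / (Para/10⁶)`.  The published formula carries a literal "×100"
  that double-counts the percent scale; the implemented form reproduces
  every published PD cell (91.5/1.20 = 76.25 etc.), so the literal reading
  is rejected.

## Training harness

SGD with momentum 0.9 and weight decay 1e-4 (coupled, PyTorch-style update);
label-smoothed cross-entropy (ε = 0.1) plus the BN-γ L1 penalty; gradient
accumulation over 4 micro-batches of 4 for an effective batch of 16;
ReduceLROnPlateau on the training loss (factor 0.1, patience 10, relative
threshold 1e-4).  The default learning rate is 0.005 (the architecture's
fuller configuration statement; an alternative 0.01 appears elsewhere and is
available as a flag).  Training aborts on a non-finite loss, keeping the last
finite state.  After training, a couple of statistics-only forward passes
refresh the BN running statistics (`recalibrate_bn`): with few epochs and a
high learning rate the exponentially averaged statistics lag the final
weights, and realigning them makes eval-mode behaviour match train-mode
behaviour.

Evaluation: subject-level stratified five-fold cross-validation (all volumes
of a subject share a fold — deliberately stricter than a scan-level split to
exclude leakage); accuracy, sensitivity, specificity, precision/recall/F1
from the confusion table, with zero-denominator metrics reported as missing
rather than coerced to 0; AUC as the Mann–Whitney pair statistic (ties 0.5);
and a one-sample Student t-test of fold accuracies against a baseline mean,
`t = (x̄ − μ0)/(s/√n)` with the n−1 sample sd and a one-sided upper-tail
p-value (the published (t, p) pairs are consistent with one-sided df = 4;
two-sided is a flag).  Oversampling (minority resampled with replacement;
majority records appear exactly once) and augmentation apply to training
folds only.

## Synthetic phantoms

Each phantom is an ellipsoidal "brain" (semi-axes ≈ 0.45 of each dimension)
of smoothed Gaussian texture (σ = 1.5 voxels, texture sd 0.08 around a base
intensity 0.7), plus voxel noise (sd 0.02), clipped to [0, 1].  Default
geometry is 73 axial slices at 96×96 in-plane (the in-plane size is a
configurable stand-in; only the slice count is anchored in the preprocessing
the network targets).  The disease class multiplies the intensity inside a
fixed subregion — the central in-plane half of the axial `signal_slab`
(default [20, 40), 0-based half-open, inferior→superior), intersected with
the brain mask — by (1 − effect_size), default effect 0.4.  Texture and
noise streams are independent of the label, so at effect 0 the two
class-conditional distributions are identical; each sample draws from a
substream indexed by `draw` under one master seed, so generation is
order-independent and bit-reproducible.

Augmentation follows the "mild" policy the training protocol calls for:
Gaussian noise injection (sd 0.01 of the intensity range, re-clipped) and
gamma correction with γ ~ U[0.8, 1.25] — magnitudes chosen once as what
keeps structural integrity intact, since only the kinds of augmentation are
prescribed.

What the phantoms do *not* emulate: anatomy, registration/skull-stripping
artefacts, scanner effects, class overlap structure of real cohorts.
Passing tests therefore demonstrate that the machinery is correct and that
the pipeline can recover a localized class signal — not that real-data
accuracies transfer.

## Interpretability

* **Occlusion**: consecutive axial slice windows (0-based, half-open) are
  replaced by a fill value (default 0 — the post-normalisation background;
  configurable) and held-out accuracy is recomputed per window; the window
  with the largest drop localizes the depth range the model relies on.
  Default grid: non-overlapping windows of 10 slices.  For the localization
  study in the acceptance suite the windows are widened to 20 slices
  (stride 10) so that one window can cover the entire 20-slice signal slab:
  a strongly separable cohort tolerates losing half the slab, which makes
  10-slice windows indecisive, whereas slab-width windows produce
  unambiguous accuracy collapses.
* **Layer importance**: mean |w| per convolutional layer, excluding channels
  removed by pruning (own output mask on pointwise rows, upstream mask on
  depthwise kernels and pointwise columns).

## Problem sizes used in the test and acceptance runs

Chosen as the smallest cohorts on which the studied effects are decisive:
the cross-validated smoke run uses 40 phantoms per class at 32×48×48 with
effect 0.4, a tiny configuration (stem 8, widths 16/32/32, LMF+ILS at the
middle stage, one dilated stage), 15 epochs at lr 0.05 (batch 4, no
accumulation — more updates per epoch suit the tiny cohort), pruning every
5 epochs.  The occlusion study trains 10 seeds on 20-per-class 40×48×48
cohorts (slab [20, 40)) with a single stratified 75/25 split.  The type-I
error study simulates fold accuracies directly as exchangeable normal draws
(200 replicates), which isolates the t-test's calibration from training
noise.

## Numerical choices and limitations

* float32 throughout; convolution is cross-correlation (the deep-learning
  dialect) with zero padding; "same" padding is `((k−1)·dilation)//2`.
* BN: biased batch variance for normalisation, unbiased in the running
  estimate, momentum 0.1, eps 1e-5 (the common convention).
* Argmax ties in prediction break toward the lower class index.
* The engine is a compact NumPy implementation tuned for small volumes and
  batch sizes; it is exact (gradient-checked against central differences)
  but not fast — full-scale training of the default 0.92 M-parameter network
  on real-sized cohorts is out of its intended scope, and real-data
  accuracy tables are not reproduced here.
* The pruning ratio applies to *remaining* channels, so s steps leave
  ≈ (1−ρ)^s of the channels (within per-layer integer rounding) until the
  parameter target binds.
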