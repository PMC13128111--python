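# Methods

This note records the modelling assumptions, numerical conventions and
design choices behind `hybridseg`, at the level of detail a maintainer or
reviewer needs to judge what the package's tests do and do not demonstrate.

## Model

The network segments 2-D axial slices of CT-like volumes.  Two encoders
run in parallel on the same 3-channel slice:

* **Local branch.** An ImageNet-style ResNet trunk — 7×7 stride-2 stem,
  3×3 stride-2 max pool, then the first three residual stages — tapped at
  strides 4/8/16.  Basic-block variants (ResNet18/34) natively produce
  (64, 128, 256) channels at the taps; bottleneck variants (ResNet50/101)
  produce (256, 512, 1024) and are mapped to the common plan by 1×1
  conv + BN + ReLU alignment blocks, so the choice of backbone changes
  capacity but never downstream shapes.  The stride-32 stage is omitted:
  the deepest fusion level is H/16, and a deeper tap would have no
  consumer.
* **Global branch.** Convolutional patch embeddings (kernel = stride = 4,
  then 2, then 2, each followed by LayerNorm) produce token grids of
  width C, 2C, 4C at strides 4/8/16.  Each stage applies one pair of
  attention blocks: plain-window multi-head self-attention (W-MSA) over
  non-overlapping M×M windows, then shifted-window attention (SW-MSA)
  after a cyclic shift of ⌊M/2⌋.  Block order is LN → attention →
  residual, LN → two-layer GELU MLP (hidden width `mlp_ratio`·dim) →
  residual.  Attention uses per-head scaling 1/√head_dim and a learned
  relative-position bias table of (2M−1)² entries indexed by pairwise
  token offsets.  The bias table is shared across heads: per-head tables
  would make the parameter count depend on the head split, and a key
  design property of this architecture — verified exactly by the tests —
  is that re-splitting dim×dim attention weights over more or fewer heads
  changes neither parameters nor (under the MAC convention below) FLOPs.
  The shifted blocks add a mask of −10⁴ to logits of token pairs whose
  members originate from different pre-shift regions; in float32 softmax
  this underflows to an exact zero weight.  No stochastic depth is used.
  Per-stage dropout (default 0.5) is applied to each stage's token grid
  after its final block.

Window divisibility is enforced, never padded: the working resolution
must satisfy `input_size % 16 == 0` and `(input_size/4) % M == 0`
(224 with M = 7; 64 with M = 4 in the reduced test configuration).

**SDI skip fusion.** Per level j the two branch outputs are concatenated
(CNN channels first), refined by CBAM, and reduced to a common width c by
1×1 conv + BN.  CBAM applies channel attention
σ(MLP(avgpool F) + MLP(maxpool F)) — a shared bias-free two-layer ReLU
MLP with hidden width channels/16 — then spatial attention
σ(conv7×7([channel-mean; channel-max])), each gating multiplicatively.
For each decoder stage i, all three reduced maps are brought to stage i's
resolution — adaptive average pooling when finer, identity when equal,
bilinear interpolation when coarser — individually smoothed by a bare 3×3
convolution (no norm or activation), and combined by element-wise
product.  The product acts as a soft AND across scales; each (i, j) pair
has its own smoothing convolution (9 total).  N = 3 scales, one per
encoder level; no fourth bottleneck-only scale exists since the encoders
emit exactly three levels.

**Decoder.** The fused stride-16 map is the bottleneck.  Four stages each
apply a kernel-2/stride-2 transposed convolution then two 3×3 conv + BN +
ReLU blocks; the fused stride-8 and stride-4 maps are concatenated ahead
of the first conv of stages 1 and 2 (concatenation, not addition — the
skip carries different semantics than the upsampled stream).  The last
two stages have no skip: the encoders provide nothing above stride 4.
Element-wise dropout (default 0.5) precedes the final 1×1 convolution to
K class logits.  With `use_sdi` off the decoder consumes the raw
concatenated levels (the plain-concatenation baseline wiring); with
`use_cbam` off the SDI reduction is bare conv + BN.

**Decoder widths.** The four stage widths are configuration-exposed
(`decoder_channels`); the default (704, 224, 96, 48) was fixed by
closed-form parameter/MAC arithmetic so the default preset sits near a
22.5M-parameter / 20.5-GFLOP budget.  The split is deliberate: a weight
in the stride-8 stage costs 28² MACs per forward while the same weight at
full resolution costs 224², so capacity is concentrated coarse and the
full-resolution stages stay thin.

## Conventions that matter

* **Bias-free convolutions ahead of BatchNorm.**  BN subtracts the
  per-channel mean, so a conv bias feeding it is exactly gradient-dead.
  All conv/transposed-conv layers followed by BN are bias-free; this also
  matches the reference ResNet layouts the parameter counts are checked
  against (ResNet34 trunk: 8,170,304 parameters, verified by closed-form
  shape arithmetic in the tests).
* **BatchNorm statistics** update only in training mode (momentum 0.1,
  unbiased running variance); inference uses running statistics.
* **Resizing.**  Adaptive average pooling partitions each input axis into
  half-open cells `[floor(r·n_in/n_out), ceil((r+1)·n_in/n_out))`;
  bilinear interpolation uses the half-pixel (align_corners = false)
  convention with edge clamping.  Both are implemented as separable
  constant matrices applied to the trailing axes, which makes them exact
  linear maps with trivially correct gradients.
* **Interpolation of data.**  Images are resized bicubically, labels
  nearest-neighbour (value sets are preserved exactly); the same pairing
  is used by the augmentation's free-rotation branch (±20°) while flips
  and right-angle rotations are exact array ops.
* **Loss.**  Soft Dice uses smoothing 1e-5 in numerator and denominator
  and averages over all K classes including background; cross-entropy is
  the per-pixel mean.  Combined loss L = λ₁·L_Dice + λ₂·L_CE with
  defaults λ₁ = λ₂ = 0.5.
* **Optimisation.**  AdamW (betas 0.9/0.999, eps 1e-8) with decoupled
  weight decay 0.01 applied to every parameter; per-epoch cosine
  annealing `lr(e) = base·(1 + cos(πe/E))/2` with floor 0.  Global
  seeding covers initialisation, dropout and data shuffling; two
  same-seed CPU runs produce bit-identical loss sequences.
* **Surface metrics.**  A voxel is a boundary point iff it is foreground
  with at least one face-adjacent background neighbour, volume edges
  counting as background (binary erosion with border value 0).  Boundary
  coordinates are scaled by voxel spacing; distances are computed in 3-D
  per volume (not averaged over 2-D slices) via k-d trees.  HD95 pools
  both directed distance sets before taking the 95th percentile with
  linear interpolation between order statistics.  Per case and class:
  absent from both prediction and truth → Dice 1, distances 0; absent
  from exactly one → Dice 0, distances excluded from means with a logged
  warning; the standalone distance functions return the spacing-scaled
  volume diagonal as a flagged worst case in that situation.
* **Accounting.**  Parameters count every learnable array (BN affine
  included, running statistics excluded).  MACs are tallied during a real
  forward pass: convolutions, transposed convolutions, linear layers, and
  the attention products QKᵀ and A·V; element-wise work, softmax,
  normalisation and resizing are uncharged, and one MAC is reported as
  one FLOP.  Under this convention FLOPs are exactly head-invariant; a
  counter that charges per-head softmax/bias work would show a
  head-dependent difference below 0.05%, which this package deliberately
  omits.

## Execution substrate

The package contains a compact numpy tensor library with reverse-mode
automatic differentiation (`hybridseg.nn`): convolution by im2col +
BLAS matmul, transposed convolution specialised to kernel = stride,
analytic backward passes for BN/LN/softmax/attention, and an AdamW
implementation.  Every primitive's gradient is validated against central
finite differences in the test suite, and the convolution forward pass
against scipy's `correlate2d`.  Everything runs in float32 on CPU.

## Synthetic phantoms

Real annotated CT cannot ship with a library, so the pipeline is
exercised on phantoms: each foreground class is an axis-aligned ellipsoid
with per-axis radii drawn uniformly from a configured range, placed
without overlap (bounded rejection sampling; failure raises a generation
error naming the constraint), voxel intensity equal to the class mean
plus Gaussian noise, clipped to [0, 1] — emulating CT whose calibrated
intensities have been windowed and normalised.  The `tiny` preset
(K = 3, 64×64×4 voxels, 1 mm isotropic, class means 0.10/0.45/0.80,
noise SD 0.02, in-plane radii 6–14 px) is the unit-test fixture; a
`synapse-like` preset provides 9 classes on 128×128×8 slabs.

What the phantoms do *not* emulate: realistic organ shapes and spatial
relationships, Hounsfield-unit distributions, partial-volume effects,
scanner artefacts, inter-slice anisotropy of real acquisitions, or
ambiguous boundaries.  Consequently the passing pipeline tests
demonstrate that the architecture, optimisation and evaluation machinery
are correct and that the model class can represent and learn
intensity-defined structures — they say nothing about segmentation
accuracy on clinical data, which would require the real benchmark
volumes and orders of magnitude more compute.

## Reduced-scale configurations

CPU-scale checks use `tiny_model_config()`: working resolution 64
(attention grids 16/8/4, window 4), token dim 16, heads (2,2,2), ResNet18
branch, SDI width 16, decoder widths (64, 48, 32, 24), dropout off.  The
capability check trains this network on the 8 axial slices of two `tiny`
phantoms for at most 300 iterations (batch 4, lr 0.001, λ₁ = λ₂ = 0.5,
seed 1234) and requires training-set foreground Dice ≥ 0.95; a typical
run reaches ≈0.99 in under two minutes on one CPU.  Training passes
through a transient all-background phase (foreground Dice near 0 for the
first ~40 iterations) before the Dice term pulls the foreground classes
out — the monotone-improvement test is therefore evaluated over a window
long enough to span that phase.

## Pretrained weights

The configuration exposes a `pretrained` flag (off by default).  For the
CNN trunk, weights can be loaded from a user-supplied npz archive of
standard ImageNet arrays; requesting pretrained weights without a path is
an explicit error, never a silent random initialisation.  No mapping is
provided for the attention branch: its conv-embedding layout
(stride 4/2/2, dims C/2C/4C) does not correspond to any published
checkpoint layout, so inventing one would be arbitrary.  Alignment
convolutions are always freshly initialised.

## Known limitations

* 2-D slice-wise only; no volumetric (3-D window) attention.
* No padding path for window-indivisible resolutions — divisibility is a
  validated precondition.
* No multi-crop or test-time augmentation; inference is one forward pass
  per slice at the working resolution.
* The CPU engine is written for clarity and correctness, not throughput;
  full-resolution (224²) training at the default width is impractical on
  CPU, which is why the capability checks run the reduced configuration.
* Real-data loaders are limited to the NIfTI `Case` layout used
  throughout; DICOM series must be converted upstream.
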