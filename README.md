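# hybridseg

A lightweight hybrid CNN + windowed-attention network for 2-D slice-wise
segmentation of CT-like volumes, written entirely on numpy (the package
ships its own compact autodiff engine, so it runs anywhere scientific
Python runs — no GPU framework required).

**Who it is for.** Researchers who want a fully inspectable, dependency-light
reference implementation of the parallel CNN/Swin-style encoder family used
in abdominal multi-organ and vascular CT segmentation: every architectural
component (windowed attention with cyclic shifts and masking, CBAM,
multi-scale skip fusion, surface-distance evaluation, parameter/FLOP
accounting) is explicit, unit-tested and runnable on a laptop CPU with
synthetic phantoms — no dataset download needed.

## The model

Two parallel encoders read the same grayscale slice (replicated to 3
channels, resized to `H×W = 224×224` by default):

* **Local branch** — a ResNet trunk (stem + first three residual stages)
  tapped at strides 4/8/16 with channels (64, 128, 256).
* **Global branch** — three stages of convolutional patch embedding
  (stride 4, 2, 2) to channels (C, 2C, 4C), each followed by a pair of
  attention blocks: window-based multi-head self-attention (W-MSA) over
  M×M token windows, then shifted-window attention (SW-MSA) with a cyclic
  shift of ⌊M/2⌋ and an additive mask, per block

      ẑ = W-MSA(LN(z)) + z,  z' = MLP(LN(ẑ)) + ẑ.

  Restricting attention to windows makes the cost O(M²·N) — linear in the
  token count N instead of quadratic.

At each level *j* the two feature maps are concatenated, refined by CBAM
(channel attention `M_c = σ(MLP(avgpool F) + MLP(maxpool F))`, then spatial
attention `M_s = σ(conv7×7[mean; max])`), and reduced to a common width *c*
by a 1×1 convolution + batch norm (the **SDI** skip module).  For every
decoder stage *i* the three reduced maps are resized to that stage's
resolution (adaptive average pooling / identity / bilinear), smoothed by a
3×3 convolution, and combined by an element-wise (Hadamard) product:

    F_fusion^i = ⨀_{j=1..3} Conv3×3( resize_i(f_j) ).

The decoder recovers full resolution by four transposed-convolution stages
with conv–BN–ReLU refinement, concatenating the fused skip maps at strides
8 and 4, with dropout after each attention stage and before the final 1×1
prediction layer (both 0.5 by default).

Training minimises `L = λ₁·L_Dice + λ₂·L_CE` (λ₁ = λ₂ = 0.5) with AdamW
and a per-epoch cosine-annealed learning rate.  Evaluation reports Dice
`2|X∩Y|/(|X|+|Y|)`, the 95th-percentile Hausdorff distance, and average
(symmetric) surface distances in millimetres, computed in 3-D per volume.

## Worked example

Architecture accounting for the default multi-organ preset (token dim
C = 64, heads (8,8,8), window 7, ResNet34 branch, SDI width 64, 9 classes):

```
$ hybridseg profile --preset synapse
# accounting convention: 1 MAC = 1 FLOP; element-wise ops uncharged
input size: 224
total: 22.34M params, 20.34G FLOPs
  cnn_encoder        8.170M     3.021G
  swin_encoder       2.245M     1.055G
  sdi                0.433M     0.501G
  decoder           11.486M    15.742G
  head               0.000M     0.022G
```

22.34 million trainable parameters and 20.34 GFLOPs (multiply-accumulate
convention) for one 224×224 forward pass; the per-submodule rows show where
capacity lives — the attention branch is small because windowing caps the
quadratic term, and most parameters sit in the coarse decoder stages where
a parameter costs few MACs.

A complete offline workflow on synthetic phantoms (blob "organs" of
distinct intensity in a noisy background):

```bash
hybridseg synth --out data --n-cases 2 --preset tiny --seed 0
hybridseg train --data data --out run \
    --set model.token_dim=16 --set model.heads=[2,2,2] \
    --set model.window_size=4 --set model.input_size=64 \
    --set model.backbone=resnet18 --set model.sdi_channels=16 \
    --set model.num_classes=3 --set model.decoder_channels=[64,48,32,24] \
    --set model.dropout_swin=0 --set model.dropout_head=0 \
    --set train.epochs=150 --set train.batch_size=4 --set train.augment=false
hybridseg predict --ckpt run/checkpoint.npz --in data --out pred
hybridseg evaluate --pred pred --gt data --out metrics.csv --classes 3
```

`metrics.csv` holds per-case per-class Dice (%), HD95/ASD/ASSD (mm);
`metrics.json` the means ± SD.  This reduced configuration fits its
training phantoms almost exactly: the reproduction script below, run with
`--seed 1`, reports a training-set foreground Dice of 0.9936 after 300
iterations and a volumetric mean HD95 of 0.0 mm / ASSD of 0.011 mm.

## Layout

| module | contents |
| --- | --- |
| `hybridseg.nn` | numpy tensor library with reverse-mode autodiff, layers, AdamW, MAC tally |
| `hybridseg.config` | typed model/train configs, presets, validation, YAML I/O |
| `hybridseg.phantom` | synthetic CT-like volumes, NIfTI I/O, slice extraction |
| `hybridseg.cnn_encoder` | ResNet trunk with stride-4/8/16 pyramid taps |
| `hybridseg.swin_encoder` | patch embedding, W-MSA/SW-MSA blocks, masks |
| `hybridseg.sdi` | CBAM and the SDI multi-scale skip fusion |
| `hybridseg.decoder` / `hybridseg.model` | decoder head and full assembly |
| `hybridseg.metrics` | Dice/CE objective, Dice/HD95/ASD/ASSD, confusion matrices |
| `hybridseg.train` | training loop, augmentation, checkpoints, volume inference |
| `hybridseg.accounting` | deterministic parameter/MAC profiling |
| `hybridseg.cli` | `hybridseg` command with synth/train/predict/evaluate/profile |

See `docs/methods.md` for the modelling assumptions, numerical conventions
and known limitations.
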