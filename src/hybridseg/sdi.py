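"""Semantics-and-Detail-Infusion (SDI) skip fusion with CBAM refinement.

Per encoder level j the CNN and attention-branch maps are concatenated along
channels, refined by CBAM (channel attention then spatial attention, each
gating multiplicatively), and reduced to a common width c by a 1x1 conv + BN.
For every decoder stage i the three reduced maps are brought to stage i's
resolution — adaptive average pooling when coming from a finer level,
identity at the same level, bilinear interpolation from a coarser level —
then each is smoothed by its own 3x3 convolution and the three are combined
by an element-wise (Hadamard) product.  The product acts as a soft logical
AND across scales: a location survives only where every scale agrees it is
salient.
"""

from __future__ import annotations

from . import nn
from .cnn_encoder import FeaturePyramid


def concat_level(f_cnn: nn.Tensor, f_swin: nn.Tensor, j: int) -> nn.Tensor:
    """Channel-concatenate one pyramid level (CNN channels first)."""
    if f_cnn.shape[0] != f_swin.shape[0] or f_cnn.shape[2:] != f_swin.shape[2:]:
        raise ValueError(
            f"level {j}: spatial/batch mismatch {f_cnn.shape} vs {f_swin.shape}")
    return nn.concat([f_cnn, f_swin], axis=1)


class ChannelAttention(nn.Module):
    """Per-channel gate from pooled descriptors through a shared MLP."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, bias=False, init_std=None)
        self.fc2 = nn.Linear(hidden, channels, bias=False, init_std=None)

    def _mlp(self, v: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.relu(self.fc1(v)))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        b, c = x.shape[0], x.shape[1]
        flat = nn.reshape(x, (b, c, -1))
        avg = nn.tmean(flat, axis=2)
        mx = nn.tmax(flat, axis=2)
        gate = nn.sigmoid(nn.add(self._mlp(avg), self._mlp(mx)))
        return nn.reshape(gate, (b, c, 1, 1))


class SpatialAttention(nn.Module):
    """Per-pixel gate from channel-pooled maps through a 7x7 convolution."""

    def __init__(self, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, 1, kernel // 2)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        avg = nn.tmean(x, axis=1, keepdims=True)
        mx = nn.tmax(x, axis=1, keepdims=True)
        return nn.sigmoid(self.conv(nn.concat([avg, mx], axis=1)))


class CBAM(nn.Module):
    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction)
        self.spatial = SpatialAttention()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.mul(x, self.channel(x))
        return nn.mul(x, self.spatial(x))


class SDIReduce(nn.Module):
    """CBAM refinement followed by 1x1 conv + BN down to c channels."""

    def __init__(self, c_in: int, c: int, use_cbam: bool, reduction: int):
        super().__init__()
        self.cbam = CBAM(c_in, reduction) if use_cbam else nn.Identity()
        self.conv = nn.Conv2d(c_in, c, 1, 1, 0, bias=False)
        self.bn = nn.BatchNorm2d(c)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.bn(self.conv(self.cbam(x)))


def sdi_resize(f_j: nn.Tensor, target_hw: tuple[int, int]) -> nn.Tensor:
    """Resize level j's map to a target stage resolution.

    Finer -> coarser uses adaptive average pooling, same size is the
    identity, coarser -> finer uses bilinear interpolation.
    """
    h, w = f_j.shape[2], f_j.shape[3]
    if (h, w) == tuple(target_hw):
        return f_j
    if h > target_hw[0]:
        return nn.adaptive_avg_pool2d(f_j, target_hw)
    return nn.bilinear_resize(f_j, target_hw)


class SDIFusion(nn.Module):
    """Full skip-fusion module over the three concatenated encoder levels."""

    def __init__(self, concat_channels: tuple[int, int, int], c: int,
                 use_cbam: bool = True, reduction: int = 16):
        super().__init__()
        if c <= 0:
            raise ValueError("sdi_channels must be positive")
        self.c = c
        for j, ch in enumerate(concat_channels):
            setattr(self, f"reduce{j + 1}",
                    SDIReduce(ch, c, use_cbam, reduction))
        # one smoothing conv per (target stage i, source level j)
        for i in range(3):
            for j in range(3):
                setattr(self, f"smooth{i + 1}{j + 1}",
                        nn.Conv2d(c, c, 3, 1, 1))

    def forward(self, concat_levels) -> FeaturePyramid:
        if len(concat_levels) != 3:
            raise ValueError("SDI expects all 3 concatenated levels")
        reduced = [getattr(self, f"reduce{j + 1}")(concat_levels[j])
                   for j in range(3)]
        fused = []
        for i in range(3):
            hw = (reduced[i].shape[2], reduced[i].shape[3])
            prod = None
            for j in range(3):
                fij = sdi_resize(reduced[j], hw)
                fij = getattr(self, f"smooth{i + 1}{j + 1}")(fij)
                prod = fij if prod is None else nn.mul(prod, fij)
            fused.append(prod)
        return FeaturePyramid(levels=tuple(fused), source="fused")
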