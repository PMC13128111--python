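"""Decoder head: transposed-conv upsampling with conv-BN-ReLU refinement.

The bottleneck is the fused stride-16 map.  Four stages each double the
resolution with a kernel-2/stride-2 transposed convolution and refine with
two 3x3 conv + BN + ReLU blocks; at strides 8 and 4 the matching fused skip
map is concatenated before refinement (the encoders provide no stride-2
features, so the last two stages have no skip input).  Element-wise dropout
sits immediately before the final 1x1 prediction convolution.

Default stage widths (704, 224, 96, 48) concentrate capacity at the coarse
stages, where parameters are cheap in multiply-accumulates, and keep the
full-resolution stages thin.
"""

from __future__ import annotations

from . import nn
from .cnn_encoder import FeaturePyramid
from .config import ModelConfig


class _ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, 1, 1, bias=False)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _UpStage(nn.Module):
    def __init__(self, c_in, skip_c, c_out):
        super().__init__()
        self.up = nn.ConvTranspose2d(c_in, c_out, 2, 2, bias=False)
        self.block1 = _ConvBNReLU(c_out + skip_c, c_out)
        self.block2 = _ConvBNReLU(c_out, c_out)

    def forward(self, x, skip=None):
        y = self.up(x)
        if skip is not None:
            if skip.shape[2:] != y.shape[2:]:
                raise ValueError(
                    f"skip resolution {skip.shape[2:]} does not match "
                    f"decoder stage {y.shape[2:]}")
            y = nn.concat([y, skip], axis=1)
        return self.block2(self.block1(y))


class DecoderHead(nn.Module):
    """Stride-16 bottleneck to full-resolution per-pixel class logits."""

    def __init__(self, cfg: ModelConfig,
                 skip_channels: tuple[int, int, int] | None = None):
        """``skip_channels`` = channels of the (stride-4, -8, -16) skip maps;
        defaults to (c, c, c) for the SDI path."""
        super().__init__()
        c = cfg.sdi_channels
        if skip_channels is None:
            skip_channels = (c, c, c)
        w1, w2, w3, w4 = cfg.decoder_channels
        self.stage1 = _UpStage(skip_channels[2], skip_channels[1], w1)
        self.stage2 = _UpStage(w1, skip_channels[0], w2)
        self.stage3 = _UpStage(w2, 0, w3)
        self.stage4 = _UpStage(w3, 0, w4)
        self.drop = nn.Dropout(cfg.dropout_head)
        self.head = nn.Conv2d(w4, cfg.num_classes, 1, 1, 0)

    def forward(self, fused: FeaturePyramid) -> nn.Tensor:
        f1, f2, f3 = fused.levels
        y = self.stage1(f3, f2)
        y = self.stage2(y, f1)
        y = self.stage3(y)
        y = self.stage4(y)
        y = self.drop(y)
        logits = self.head(y)
        return logits


def decode(head: DecoderHead, fused: FeaturePyramid) -> nn.Tensor:
    return head(fused)


def dropout_policy(cfg: ModelConfig) -> list[tuple[str, float]]:
    """The (site, rate) pairs in effect for a configuration."""
    for name in ("dropout_swin", "dropout_head"):
        r = getattr(cfg, name)
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} rate {r} outside [0, 1]")
    sites = []
    if cfg.dropout_swin > 0:
        sites.append(("swin_stages", cfg.dropout_swin))
    if cfg.dropout_head > 0:
        sites.append(("pre_head", cfg.dropout_head))
    return sites
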