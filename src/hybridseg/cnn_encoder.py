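"""Local-detail branch: a residual-network trunk with three pyramid taps.

The trunk is the standard ImageNet ResNet stem plus its first three residual
stages, i.e. everything up to stride 16.  Taps sit at the outputs of the
stride-4, stride-8 and stride-16 stages; the stride-32 stage is omitted
because the deepest fusion level of the network is H/16.  Basic-block
variants (ResNet18/34) natively emit (64, 128, 256) channels at the taps;
bottleneck variants (ResNet50/101) emit (256, 512, 1024) and are brought to
the common (64, 128, 256) layout by 1x1 conv + BN + ReLU alignment blocks,
so swapping the backbone never changes downstream shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn

# residual-block counts of the first three stages per variant
_STAGE_BLOCKS = {
    "resnet18": (2, 2, 2),
    "resnet34": (3, 4, 6),
    "resnet50": (3, 4, 6),
    "resnet101": (3, 4, 23),
}
_BOTTLENECK = {"resnet18": False, "resnet34": False,
               "resnet50": True, "resnet101": True}

PYRAMID_CHANNELS = (64, 128, 256)


@dataclass
class FeaturePyramid:
    """Three feature maps at strides 4/8/16 sharing one batch extent."""

    levels: tuple
    source: str

    def __post_init__(self):
        if len(self.levels) != 3:
            raise ValueError("a feature pyramid has exactly 3 levels")
        shapes = [l.shape for l in self.levels]
        b = shapes[0][0]
        for j in range(3):
            if shapes[j][0] != b:
                raise ValueError("pyramid levels disagree on batch extent")
        for j in range(2):
            if shapes[j][2] != 2 * shapes[j + 1][2] or \
               shapes[j][3] != 2 * shapes[j + 1][3]:
                raise ValueError("pyramid spatial sizes must halve per level")

    @property
    def channels(self) -> tuple[int, int, int]:
        return tuple(l.shape[1] for l in self.levels)


class BasicBlock(nn.Module):
    def __init__(self, c_in, c_out, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, 1, 1, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, stride, 0, bias=False)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def forward(self, x):
        idt = x
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        if self.down_conv is not None:
            idt = self.down_bn(self.down_conv(x))
        return nn.relu(y + idt)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, c_in, width, stride=1):
        super().__init__()
        c_out = width * self.expansion
        self.conv1 = nn.Conv2d(c_in, width, 1, 1, 0, bias=False)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride, 1, bias=False)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, c_out, 1, 1, 0, bias=False)
        self.bn3 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, stride, 0, bias=False)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def forward(self, x):
        idt = x
        y = nn.relu(self.bn1(self.conv1(x)))
        y = nn.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        if self.down_conv is not None:
            idt = self.down_bn(self.down_conv(x))
        return nn.relu(y + idt)


class _Align(nn.Module):
    """1x1 conv + BN + ReLU bringing bottleneck channels to the common plan."""

    def __init__(self, c_in, c_out):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 1, 1, 0, bias=False)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class CNNEncoder(nn.Module):
    """ResNet trunk emitting a stride-4/8/16 pyramid of (64, 128, 256) channels."""

    def __init__(self, backbone: str = "resnet34", pretrained: bool = False,
                 weights_path: str | None = None):
        super().__init__()
        if backbone not in _STAGE_BLOCKS:
            raise ValueError(f"unknown backbone {backbone!r}; "
                             f"choose one of {tuple(_STAGE_BLOCKS)}")
        if pretrained and weights_path is None:
            raise ValueError(
                "pretrained=True requires an explicit weights_path; refusing "
                "to silently fall back to random initialisation")
        self.backbone = backbone
        bottleneck = _BOTTLENECK[backbone]
        blocks = _STAGE_BLOCKS[backbone]

        self.conv1 = nn.Conv2d(3, 64, 7, 2, 3, bias=False)
        self.bn1 = nn.BatchNorm2d(64)

        widths = (64, 128, 256)
        c_in = 64
        stages = []
        for s, (w, nblocks) in enumerate(zip(widths, blocks)):
            stride = 1 if s == 0 else 2
            mods = []
            for i in range(nblocks):
                if bottleneck:
                    mods.append(Bottleneck(c_in, w, stride if i == 0 else 1))
                    c_in = w * Bottleneck.expansion
                else:
                    mods.append(BasicBlock(c_in, w, stride if i == 0 else 1))
                    c_in = w
            stages.append(nn.Sequential(*mods))
        self.stage1, self.stage2, self.stage3 = stages

        if bottleneck:
            self.align1 = _Align(256, 64)
            self.align2 = _Align(512, 128)
            self.align3 = _Align(1024, 256)
        else:
            self.align1 = self.align2 = self.align3 = None

        if pretrained:
            self._load_imagenet(weights_path)

    def _load_imagenet(self, weights_path: str) -> None:
        """Load trunk weights from an ``npz`` of torchvision-style arrays.

        Alignment convolutions are always freshly initialised.
        """
        import numpy as np

        archive = np.load(weights_path)
        own = dict(self.named_parameters())
        loaded = 0
        for name, value in archive.items():
            if name in own and own[name].data.shape == value.shape:
                own[name].data[...] = value
                loaded += 1
        if loaded == 0:
            raise ValueError(f"no matching trunk weights found in {weights_path}")

    def forward(self, x) -> FeaturePyramid:
        if x.shape[1] != 3:
            raise ValueError(f"expected 3 input channels, got {x.shape[1]}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input spatial size must be divisible by 16")
        y = nn.relu(self.bn1(self.conv1(x)))
        y = nn.max_pool2d(y, 3, 2, 1)
        f1 = self.stage1(y)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        if self.align1 is not None:
            f1, f2, f3 = self.align1(f1), self.align2(f2), self.align3(f3)
        return FeaturePyramid(levels=(f1, f2, f3), source="cnn")


def build_cnn_encoder(backbone: str, pretrained: bool = False,
                      weights_path: str | None = None) -> CNNEncoder:
    return CNNEncoder(backbone, pretrained, weights_path)


def cnn_forward(encoder: CNNEncoder, batch) -> FeaturePyramid:
    return encoder(batch)
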