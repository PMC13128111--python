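"""Full network assembly: parallel encoders -> skip fusion -> decoder."""

from __future__ import annotations

from . import nn
from .cnn_encoder import CNNEncoder, PYRAMID_CHANNELS
from .config import ModelConfig, validate_config
from .decoder import DecoderHead
from .sdi import SDIFusion, concat_level
from .swin_encoder import SwinEncoder


class HybridSegNet(nn.Module):
    """Parallel CNN + windowed-attention segmentation network.

    With ``use_sdi`` the concatenated encoder levels pass through the SDI
    module and the decoder sees three c-channel skip maps; without it
    (the plain-concatenation baseline wiring) the decoder consumes the raw
    concatenated levels directly.
    """

    def __init__(self, cfg: ModelConfig, pretrained_cnn_path: str | None = None):
        super().__init__()
        violations = validate_config(cfg)
        if violations:
            raise ValueError("invalid model config: " + "; ".join(violations))
        self.cfg = cfg
        self.cnn = CNNEncoder(cfg.backbone, pretrained=cfg.pretrained,
                              weights_path=pretrained_cnn_path)
        self.swin = SwinEncoder(cfg)
        c = cfg.token_dim
        concat_ch = tuple(PYRAMID_CHANNELS[j] + c * 2 ** j for j in range(3))
        if cfg.use_sdi:
            self.sdi = SDIFusion(concat_ch, cfg.sdi_channels,
                                 cfg.use_cbam, cfg.cbam_reduction)
            skip_ch = (cfg.sdi_channels,) * 3
        else:
            self.sdi = None
            skip_ch = concat_ch
        self.decoder = DecoderHead(cfg, skip_channels=skip_ch)

    # exposed for per-submodule accounting
    def forward_parts(self, x: nn.Tensor):
        p_cnn = self.cnn(x)
        p_swin = self.swin(x)
        cat = [concat_level(p_cnn.levels[j], p_swin.levels[j], j + 1)
               for j in range(3)]
        if self.sdi is not None:
            fused = self.sdi(cat)
        else:
            from .cnn_encoder import FeaturePyramid
            fused = FeaturePyramid(levels=tuple(cat), source="fused")
        logits = self.decoder(fused)
        return p_cnn, p_swin, fused, logits

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.forward_parts(x)[-1]


def build_model(cfg: ModelConfig, seed: int | None = None) -> HybridSegNet:
    """Construct the network, optionally reseeding parameter initialisation."""
    if seed is not None:
        nn.seed_all(seed)
    return HybridSegNet(cfg)
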