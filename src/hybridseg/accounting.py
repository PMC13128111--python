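"""Deterministic parameter and multiply-accumulate (MAC) accounting.

Parameters are counted over every learnable array (batch-norm affine terms
included, running statistics excluded).  MACs are measured by running one
forward pass at the stated input size with the engine's tally active:
convolutions, transposed convolutions, linear layers and the two attention
matrix products (QK^T and attention*V) are charged; element-wise work,
softmax, normalisation statistics and spatial resizing are not.  One MAC is
reported as one FLOP — the convention of the common model profilers whose
magnitudes this accounting is meant to be comparable with.  Under it, FLOP
totals are exactly invariant to the head split (weights are dim x dim
however they are split, and per-head softmax/bias work is uncharged).

Counts are pure functions of (ModelConfig, input_size): dropout is
inactive in the profiling pass and no randomness enters the tally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig, validate_config
from .model import HybridSegNet, build_model
from .sdi import concat_level

SUBMODULES = ("cnn_encoder", "swin_encoder", "sdi", "decoder", "head")


@dataclass
class ParamFlopReport:
    total_params: int
    total_macs: int
    per_submodule: dict[str, tuple[int, int]]
    input_size: int
    convention: str = "1 MAC = 1 FLOP; element-wise ops uncharged"

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    @property
    def flops_g(self) -> float:
        return self.total_macs / 1e9

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "input_size": self.input_size,
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "params_m": round(self.params_m, 4),
            "flops_g": round(self.flops_g, 4),
            "per_submodule": {k: {"params": p, "macs": m}
                              for k, (p, m) in self.per_submodule.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable weights (BN affine included, running stats not)."""
    return model.num_parameters()


def count_macs(model: HybridSegNet, input_size: int) -> int:
    """MACs of one forward pass at batch 1 and the given input size."""
    model.eval()
    x = nn.Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    tally = nn.MacTally()
    with nn.no_grad(), nn.track_macs(tally):
        model(x)
    return tally.n


def profile_report(model_cfg: ModelConfig, input_size: int | None = None,
                   model: HybridSegNet | None = None) -> ParamFlopReport:
    """Build the model and report totals plus a per-submodule breakdown."""
    violations = validate_config(model_cfg)
    if violations:
        raise ValueError("invalid model config: " + "; ".join(violations))
    if input_size is None:
        input_size = model_cfg.input_size
    if model is None:
        model = build_model(model_cfg, seed=0)
    model.eval()

    head = model.decoder.head
    decoder_params = count_parameters(model.decoder) - count_parameters(head)
    params = {
        "cnn_encoder": count_parameters(model.cnn),
        "swin_encoder": count_parameters(model.swin),
        "sdi": count_parameters(model.sdi) if model.sdi is not None else 0,
        "decoder": decoder_params,
        "head": count_parameters(head),
    }

    x = nn.Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    macs: dict[str, int] = {}
    with nn.no_grad():
        with nn.track_macs(nn.MacTally()) as t:
            p_cnn = model.cnn(x)
        macs["cnn_encoder"] = t.n
        with nn.track_macs(nn.MacTally()) as t:
            p_swin = model.swin(x)
        macs["swin_encoder"] = t.n
        cat = [concat_level(p_cnn.levels[j], p_swin.levels[j], j + 1)
               for j in range(3)]
        if model.sdi is not None:
            with nn.track_macs(nn.MacTally()) as t:
                fused = model.sdi(cat)
            macs["sdi"] = t.n
        else:
            from .cnn_encoder import FeaturePyramid
            fused = FeaturePyramid(levels=tuple(cat), source="fused")
            macs["sdi"] = 0
        with nn.track_macs(nn.MacTally()) as t:
            model.decoder(fused)
        total_dec = t.n
    macs["head"] = _head_macs(head, input_size)
    macs["decoder"] = total_dec - macs["head"]

    total_p = sum(params.values())
    total_m = sum(macs.values())
    assert total_p == count_parameters(model)
    return ParamFlopReport(
        total_params=total_p, total_macs=total_m,
        per_submodule={k: (params[k], macs[k]) for k in SUBMODULES},
        input_size=input_size)


def _head_macs(head: nn.Conv2d, input_size: int) -> int:
    o, c, kh, kw = head.weight.data.shape
    return o * c * kh * kw * input_size * input_size
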