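"""Typed model/training configuration, presets and validation.

Two presets mirror the experimental settings the network was developed for:

* ``synapse`` — abdominal multi-organ CT (8 organs + background, K=9),
  SDI width c=64, 224x224 working resolution, ResNet34 local branch.
* ``avt`` — aortic-vessel-tree CTA (vessel vs background, K=2), SDI width
  c=96, otherwise identical.

Configs serialise to a YAML file with two top-level sections (``model`` and
``train``); unknown keys are tolerated with a warning so files written by
newer versions still load.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("hybridseg")

BACKBONES = ("resnet18", "resnet34", "resnet50", "resnet101")
PRESETS = ("synapse", "avt")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``token_dim`` is the embedding width C of the first attention stage
    (later stages use 2C and 4C); ``depths`` counts attention blocks per
    stage and must be even, since blocks alternate plain-window (W-MSA) and
    shifted-window (SW-MSA) attention; ``window_size`` M is the token count
    per window side; ``sdi_channels`` c is the common width every fused skip
    level is reduced to.
    """

    token_dim: int = 64
    heads: tuple[int, int, int] = (8, 8, 8)
    depths: tuple[int, int, int] = (2, 2, 2)
    window_size: int = 7
    mlp_ratio: float = 4.0
    backbone: str = "resnet34"
    sdi_channels: int = 64
    num_classes: int = 9
    input_size: int = 224
    dropout_swin: float = 0.5
    dropout_head: float = 0.5
    cbam_reduction: int = 16
    use_cbam: bool = True
    use_sdi: bool = True
    decoder_channels: tuple[int, int, int, int] = (704, 224, 96, 48)
    pretrained: bool = False


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 250
    base_lr: float = 0.001
    lambda_dice: float = 0.5
    lambda_ce: float = 0.5
    seed: int = 1234
    augment: bool = True
    weight_decay: float = 0.01
    lr_schedule: str = "cosine"


def default_config(preset: str) -> tuple[ModelConfig, TrainConfig]:
    """Return the (model, train) configuration pair for a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {PRESETS}")
    model = ModelConfig()
    train = TrainConfig()
    if preset == "avt":
        model.sdi_channels = 96
        model.num_classes = 2
    return model, train


def tiny_model_config() -> ModelConfig:
    """Reduced configuration for desk-scale capability checks.

    Working resolution 64 (so the attention grids are 16/8/4 with window
    size 4), narrow token dim and decoder, ResNet18 local branch, dropout
    off.  Pairs with the ``tiny`` phantom preset: small enough to train on
    a CPU in minutes while exercising every architectural component.
    """
    return ModelConfig(token_dim=16, heads=(2, 2, 2), window_size=4,
                       backbone="resnet18", sdi_channels=16, num_classes=3,
                       input_size=64, dropout_swin=0.0, dropout_head=0.0,
                       decoder_channels=(64, 48, 32, 24))


def validate_config(m: ModelConfig) -> list[str]:
    """Return a list of invariant violations (empty iff the config is valid)."""
    v: list[str] = []
    if m.token_dim <= 0:
        v.append("token_dim: must be positive")
    if len(m.heads) != 3 or any(h <= 0 for h in m.heads):
        v.append("heads: must be a triple of positive integers")
    else:
        for s, h in enumerate(m.heads):
            if (m.token_dim * 2 ** s) % h != 0:
                v.append(f"heads: stage {s + 1} head count {h} does not divide "
                         f"channel count {m.token_dim * 2 ** s}")
    if len(m.depths) != 3 or any(d <= 0 for d in m.depths):
        v.append("depths: must be a triple of positive integers")
    elif any(d % 2 != 0 for d in m.depths):
        v.append("depths: must be even (W-MSA/SW-MSA blocks alternate in pairs)")
    if m.window_size <= 0:
        v.append("window_size: must be positive")
    if m.input_size <= 0 or m.input_size % 16 != 0:
        v.append(f"input_size: {m.input_size} is not divisible by 16")
    elif m.window_size > 0:
        for s in range(3):
            res = m.input_size // (4 * 2 ** s)
            if res % m.window_size != 0:
                v.append(f"window_size: stage {s + 1} grid {res} is not "
                         f"divisible by window size {m.window_size}")
    if m.backbone not in BACKBONES:
        v.append(f"backbone: {m.backbone!r} not in {BACKBONES}")
    if m.use_sdi and m.sdi_channels <= 0:
        v.append("sdi_channels: must be positive when use_sdi is set")
    if m.num_classes < 2:
        v.append("num_classes: must be >= 2 (foreground + background)")
    for name in ("dropout_swin", "dropout_head"):
        r = getattr(m, name)
        if not (0.0 <= r <= 1.0):
            v.append(f"{name}: rate {r} outside [0, 1]")
    if m.cbam_reduction < 1:
        v.append("cbam_reduction: must be >= 1")
    if m.mlp_ratio <= 0:
        v.append("mlp_ratio: must be positive")
    if len(m.decoder_channels) != 4 or any(c <= 0 for c in m.decoder_channels):
        v.append("decoder_channels: must be four positive widths")
    return v


def validate_train_config(t: TrainConfig) -> list[str]:
    v: list[str] = []
    if t.batch_size <= 0:
        v.append("batch_size: must be positive")
    if t.epochs <= 0:
        v.append("epochs: must be positive")
    if t.base_lr <= 0:
        v.append("base_lr: must be positive")
    for name in ("lambda_dice", "lambda_ce"):
        w = getattr(t, name)
        if not (0.0 <= w <= 1.0):
            v.append(f"{name}: weight {w} outside [0, 1]")
    if t.lambda_dice + t.lambda_ce <= 0:
        v.append("lambda_dice + lambda_ce must be > 0")
    if t.weight_decay < 0:
        v.append("weight_decay: must be nonnegative")
    return v


class ConfigError(ValueError):
    pass


def _from_section(cls, section: dict, name: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in section.items():
        if key not in fields:
            logger.warning("config section %r: ignoring unknown key %r", name, key)
            continue
        f = fields[key]
        if f.type.startswith("tuple") and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    missing = [k for k in fields
               if k not in kwargs and fields[k].default is dataclasses.MISSING
               and fields[k].default_factory is dataclasses.MISSING]
    if missing:
        raise ConfigError(f"config section {name!r} missing required fields: {missing}")
    return cls(**kwargs)


def load_config(path) -> tuple[ModelConfig, TrainConfig]:
    """Load a two-section (model/train) YAML configuration file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} must be a mapping with "
                          "'model' and 'train' sections")
    for section in ("model", "train"):
        if section not in doc:
            raise ConfigError(f"config file {path} missing section {section!r}")
    if "token_dim" not in doc["model"]:
        raise ConfigError(f"config file {path}: model section missing token_dim")
    model = _from_section(ModelConfig, doc["model"], "model")
    train = _from_section(TrainConfig, doc["train"], "train")
    return model, train


def save_config(model: ModelConfig, train: TrainConfig, path) -> None:
    def plain(dc):
        d = dataclasses.asdict(dc)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    with open(path, "w") as fh:
        yaml.safe_dump({"model": plain(model), "train": plain(train)}, fh,
                       sort_keys=False)


def apply_overrides(model: ModelConfig, train: TrainConfig,
                    overrides: list[str]) -> None:
    """Apply ``key=value`` overrides (keys like ``model.token_dim``)."""
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        key = key.strip()
        if "." in key:
            section, key = key.split(".", 1)
        else:
            section = "model" if hasattr(ModelConfig, key) or \
                key in {f.name for f in dataclasses.fields(ModelConfig)} else "train"
        target = model if section == "model" else train
        fields = {f.name: f for f in dataclasses.fields(type(target))}
        if key not in fields:
            raise ConfigError(f"unknown config field {section}.{key}")
        value = yaml.safe_load(raw)
        if isinstance(value, list):
            value = tuple(value)
        setattr(target, key, value)
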