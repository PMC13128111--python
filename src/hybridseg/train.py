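"""Training loop, augmentation, checkpointing and slice-wise volume inference.

Training follows the slice-wise 2-D protocol: volumes are cut into axial
slices, resized to the square working resolution, optionally augmented
(random flips/right-angle rotations, else a small free rotation), and
optimised with AdamW under the combined Dice + cross-entropy objective with
per-epoch cosine-annealed learning rate.  Inference runs the trained model
on every axial slice of a volume, takes the per-pixel argmax and restacks
the nearest-neighbour-resized label slices into a volume aligned with the
input.

Checkpoints are single ``.npz`` archives holding model weights and buffers,
optimiser state, the epoch index, an RNG snapshot and a YAML snapshot of
both configs, so a reloaded model reproduces inference bit-exactly and
training can resume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import nn
from .config import (ModelConfig, TrainConfig, load_config, save_config,
                     validate_train_config)
from .metrics import LossWeights, combined_loss, dice_coefficient
from .model import HybridSegNet, build_model
from .phantom import Case, list_cases, make_training_slices, read_case, \
    resize_image2d, resize_label2d

logger = logging.getLogger("hybridseg")


def cosine_lr(epoch: int, total_epochs: int, base_lr: float) -> float:
    """Per-epoch cosine annealing from ``base_lr`` down to 0."""
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    return base_lr * (1.0 + math.cos(math.pi * epoch / total_epochs)) / 2.0


def augment_pair(image2d: np.ndarray, label2d: np.ndarray,
                 rng: np.random.Generator):
    """Random flip/right-angle rotation, or a small free rotation.

    ``image2d`` is (C, H, W); the label is transformed identically with
    nearest-neighbour resampling so the pair stays aligned.
    """
    if image2d.shape[-2:] != label2d.shape:
        raise ValueError("image/label shapes differ")
    if rng.random() < 0.5:
        img, lab = image2d, label2d
        if rng.random() < 0.5:
            axis = int(rng.integers(0, 2))
            img = np.flip(img, axis=axis + 1)
            lab = np.flip(lab, axis=axis)
        k = int(rng.integers(0, 4))
        if k:
            img = np.rot90(img, k, axes=(1, 2))
            lab = np.rot90(lab, k, axes=(0, 1))
        return np.ascontiguousarray(img), np.ascontiguousarray(lab)
    angle = float(rng.uniform(-20.0, 20.0))
    img = np.stack([ndimage.rotate(c, angle, reshape=False, order=3,
                                   mode="nearest") for c in image2d])
    lab = ndimage.rotate(label2d, angle, reshape=False, order=0,
                         mode="nearest")
    return img.astype(np.float32), lab


@dataclass
class TrainLog:
    iter_loss: list[float] = field(default_factory=list)
    epoch_lr: list[float] = field(default_factory=list)
    epoch_loss: list[float] = field(default_factory=list)
    epoch_train_dsc: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: HybridSegNet, optimizer: nn.AdamW | None,
                    epoch: int, model_cfg: ModelConfig,
                    train_cfg: TrainConfig) -> None:
    import tempfile

    # reuse the YAML config writer for the snapshot
    with tempfile.NamedTemporaryFile("r", suffix=".yaml", delete=False) as fh:
        save_config(model_cfg, train_cfg, fh.name)
        snapshot = open(fh.name).read()
    arrays = {"param::" + k: v for k, v in model.state_dict().items()
              if not k.startswith("buffer::")}
    arrays.update({"state_" + k: v for k, v in model.state_dict().items()
                   if k.startswith("buffer::")})
    payload = dict(arrays)
    payload["meta::epoch"] = np.array(epoch)
    payload["meta::config_yaml"] = np.array(snapshot)
    payload["meta::rng"] = np.frombuffer(
        yaml.safe_dump(nn.get_rng().bit_generator.state).encode(), dtype=np.uint8)
    if optimizer is not None:
        payload["meta::opt_t"] = np.array(optimizer.t)
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            payload[f"opt::m{i}"] = m
            payload[f"opt::v{i}"] = v
    np.savez(path, **payload)


def load_checkpoint(path, pretrained_cnn_path: str | None = None):
    """Rebuild (model, model_cfg, train_cfg, epoch, raw archive) from disk."""
    import tempfile

    archive = np.load(path, allow_pickle=False)
    snapshot = str(archive["meta::config_yaml"])
    with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
        fh.write(snapshot)
        cfg_path = fh.name
    model_cfg, train_cfg = load_config(cfg_path)
    model = HybridSegNet(model_cfg, pretrained_cnn_path)
    state = {}
    for key in archive.files:
        if key.startswith("param::"):
            state[key[len("param::"):]] = archive[key]
        elif key.startswith("state_buffer::"):
            state[key[len("state_"):]] = archive[key]
    model.load_state_dict(state)
    epoch = int(archive["meta::epoch"])
    return model, model_cfg, train_cfg, epoch, archive


def restore_optimizer(optimizer: nn.AdamW, archive) -> None:
    if "meta::opt_t" not in archive.files:
        return
    optimizer.t = int(archive["meta::opt_t"])
    for i in range(len(optimizer.m)):
        optimizer.m[i][...] = archive[f"opt::m{i}"]
        optimizer.v[i][...] = archive[f"opt::v{i}"]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _collect_slices(cases: list[Case], input_size: int):
    images, labels = [], []
    for case in cases:
        for img, lab in make_training_slices(case, input_size):
            images.append(img)
            labels.append(lab)
    return np.stack(images), np.stack(labels)


def _foreground_dsc(model: HybridSegNet, images: np.ndarray,
                    labels: np.ndarray, batch_size: int) -> float:
    """Mean foreground Dice over a slice set at working resolution."""
    was_training = model.training
    model.eval()
    preds = []
    with nn.no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(nn.Tensor(images[i:i + batch_size]))
            preds.append(logits.data.argmax(axis=1))
    model.train(was_training)
    pred = np.concatenate(preds)
    k = model.cfg.num_classes
    dscs = []
    for c in range(1, k):
        if not (labels == c).any() and not (pred == c).any():
            continue
        dscs.append(dice_coefficient(pred == c, labels == c))
    return float(np.mean(dscs)) if dscs else float("nan")


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data_dir,
          out_dir=None, cases: list[Case] | None = None,
          max_iterations: int | None = None,
          model: HybridSegNet | None = None,
          track_train_dsc: bool = False):
    """Train on every axial slice of the cases under ``data_dir``.

    Returns (model, TrainLog).  ``cases`` may be passed directly to bypass
    disk I/O; ``max_iterations`` caps total optimisation steps (used by the
    small-scale capability checks).
    """
    violations = validate_train_config(train_cfg)
    if violations:
        raise ValueError("invalid train config: " + "; ".join(violations))
    nn.seed_all(train_cfg.seed)
    if cases is None:
        ids = list_cases(data_dir)
        if not ids:
            raise ValueError(f"no cases found under {data_dir}")
        cases = [read_case(data_dir, i) for i in ids]
    if not cases:
        raise ValueError("empty dataset")
    images, labels = _collect_slices(cases, model_cfg.input_size)
    logger.info("training on %d slices from %d cases", len(images), len(cases))

    if model is None:
        model = build_model(model_cfg)
    model.train()
    optimizer = nn.AdamW(model.parameters(), lr=train_cfg.base_lr,
                         weight_decay=train_cfg.weight_decay)
    weights = LossWeights(train_cfg.lambda_dice, train_cfg.lambda_ce)
    data_rng = np.random.default_rng(train_cfg.seed + 1)
    aug_rng = np.random.default_rng(train_cfg.seed + 2)

    log = TrainLog()
    iteration = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_schedule == "cosine":
            lr = cosine_lr(epoch, train_cfg.epochs, train_cfg.base_lr)
        elif train_cfg.lr_schedule == "constant":
            lr = train_cfg.base_lr
        else:
            raise ValueError(f"unknown lr_schedule {train_cfg.lr_schedule!r}")
        optimizer.lr = lr
        log.epoch_lr.append(lr)
        order = data_rng.permutation(len(images))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            batch_img = images[idx]
            batch_lab = labels[idx]
            if train_cfg.augment:
                pairs = [augment_pair(batch_img[i], batch_lab[i], aug_rng)
                         for i in range(len(idx))]
                batch_img = np.stack([p[0] for p in pairs])
                batch_lab = np.stack([p[1] for p in pairs])
            logits = model(nn.Tensor(batch_img))
            loss = combined_loss(logits, batch_lab, weights)
            lval = loss.item()
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite loss {lval} at epoch {epoch} iteration "
                    f"{iteration}; aborting")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            log.iter_loss.append(lval)
            epoch_losses.append(lval)
            iteration += 1
            if max_iterations is not None and iteration >= max_iterations:
                break
        log.epoch_loss.append(float(np.mean(epoch_losses)))
        if track_train_dsc:
            log.epoch_train_dsc.append(
                _foreground_dsc(model, images, labels, train_cfg.batch_size))
        logger.info("epoch %d/%d lr %.6f loss %.4f", epoch + 1,
                    train_cfg.epochs, lr, log.epoch_loss[-1])
        if out_dir is not None:
            save_checkpoint(out_dir / "checkpoint.npz", model, optimizer,
                            epoch, model_cfg, train_cfg)
        if max_iterations is not None and iteration >= max_iterations:
            break
    return model, log


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_volume(model: HybridSegNet, case: Case,
                   batch_size: int = 8) -> np.ndarray:
    """Slice-wise inference: resize, forward, argmax, resize back, restack."""
    case.validate()
    cfg = model.cfg
    size = cfg.input_size
    model.eval()
    slices = [np.repeat(resize_image2d(case.image[s], (size, size))[None],
                        3, axis=0)
              for s in range(case.image.shape[0])]
    stack = np.stack(slices)
    preds = []
    with nn.no_grad():
        for i in range(0, len(stack), batch_size):
            logits = model(nn.Tensor(stack[i:i + batch_size]))
            preds.append(logits.data.argmax(axis=1).astype(np.int16))
    pred = np.concatenate(preds)
    out = np.stack([resize_label2d(pred[s], case.image.shape[1:])
                    for s in range(pred.shape[0])])
    return out.astype(np.int16)
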