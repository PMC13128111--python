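"""Training objective and evaluation metrics.

Objective: L = lambda_dice * L_Dice + lambda_ce * L_CE, where L_Dice is one
minus the smoothed soft Dice between softmax probabilities and one-hot
labels averaged over all K classes (background included) and L_CE is mean
per-pixel cross-entropy.

Evaluation: per-class Dice (2|X∩Y| / (|X|+|Y|)), 95th-percentile Hausdorff
distance, average surface distance (ASD) and average symmetric surface
distance (ASSD), all surface metrics in millimetres using the voxel
spacing, plus a KxK pixel confusion matrix.  Distances are computed in 3-D
per volume.  A voxel is a boundary point iff it is foreground with at least
one face-adjacent background neighbour (volume edges count as background).

Empty-mask conventions (per case and class): a class absent from both
prediction and truth scores Dice 1 and distance 0; absent from exactly one
scores Dice 0 and is excluded from mean distance aggregation with a logged
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import nn

logger = logging.getLogger("hybridseg")

DICE_SMOOTH = 1e-5


# ---------------------------------------------------------------------------
# training losses (differentiable)
# ---------------------------------------------------------------------------


@dataclass
class LossWeights:
    lambda_dice: float = 0.5
    lambda_ce: float = 0.5

    def __post_init__(self):
        if self.lambda_dice < 0 or self.lambda_ce < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_dice + self.lambda_ce <= 0:
            raise ValueError("at least one loss weight must be positive")


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"label values outside [0, {k})")
    eye = np.eye(k, dtype=np.float32)
    return np.moveaxis(eye[labels], -1, 1)          # (B, K, H, W)


def soft_dice_loss(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """1 - mean over all K classes of smoothed soft Dice."""
    k = logits.shape[1]
    onehot = nn.Tensor(_one_hot(labels, k))
    probs = nn.softmax(logits, axis=1)
    inter = nn.tsum(nn.mul(probs, onehot), axis=(0, 2, 3))
    sizes = nn.add(nn.tsum(probs, axis=(0, 2, 3)),
                   nn.tsum(onehot, axis=(0, 2, 3)))
    dice = (2.0 * inter + DICE_SMOOTH) / (sizes + DICE_SMOOTH)
    return 1.0 - nn.tmean(dice)


def cross_entropy_loss(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    k = logits.shape[1]
    onehot = nn.Tensor(_one_hot(labels, k))
    logp = nn.log_softmax(logits, axis=1)
    per_pixel = nn.tsum(nn.mul(onehot, logp), axis=1)
    return -nn.tmean(per_pixel)


def combined_loss(logits: nn.Tensor, labels: np.ndarray,
                  w: LossWeights) -> nn.Tensor:
    loss = nn.Tensor(0.0)
    if w.lambda_dice:
        loss = loss + w.lambda_dice * soft_dice_loss(logits, labels)
    if w.lambda_ce:
        loss = loss + w.lambda_ce * cross_entropy_loss(logits, labels)
    return loss


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def dice_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """2|X∩Y| / (|X|+|Y|); both masks empty counts as perfect agreement."""
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    x = x.astype(bool)
    y = y.astype(bool)
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(x, y).sum()) / total


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, k: int) -> np.ndarray:
    """KxK counts; entry (t, p) counts pixels with truth t predicted p."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth sizes differ")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.size and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{name} labels outside [0, {k})")
    return np.bincount(truth.astype(np.int64) * k + pred.astype(np.int64),
                       minlength=k * k).reshape(k, k)


# ---------------------------------------------------------------------------
# surface metrics
# ---------------------------------------------------------------------------

_FACE_STRUCT3 = ndimage.generate_binary_structure(3, 1)


def boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Coordinates (mm) of foreground voxels with a face-adjacent background
    (or volume-edge) neighbour."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 2:
        mask = mask[None]
        spacing = (1.0, *spacing) if len(spacing) == 2 else spacing
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT3,
                                      border_value=0)
    surface = mask & ~interior
    pts = np.argwhere(surface).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return np.asarray(d, dtype=np.float64)


def _surface_pair(x, y, spacing):
    sx = boundary_points(x, spacing)
    sy = boundary_points(y, spacing)
    return sx, sy


def hd95(x: np.ndarray, y: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of the pooled directed boundary distances (mm)."""
    handled = _empty_convention(x, y, spacing, "HD95")
    if handled is not None:
        return handled
    sx, sy = _surface_pair(x, y, spacing)
    pooled = np.concatenate([_directed_distances(sx, sy),
                             _directed_distances(sy, sx)])
    return float(np.percentile(pooled, 95, method="linear"))


def asd(x: np.ndarray, y: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean distance from predicted-boundary points to the truth boundary."""
    handled = _empty_convention(x, y, spacing, "ASD")
    if handled is not None:
        return handled
    sx, sy = _surface_pair(x, y, spacing)
    return float(_directed_distances(sx, sy).mean())


def assd(x: np.ndarray, y: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric average of the two directed mean surface distances."""
    handled = _empty_convention(x, y, spacing, "ASSD")
    if handled is not None:
        return handled
    return 0.5 * (asd(x, y, spacing) + asd(y, x, spacing))


def _empty_convention(x, y, spacing, name: str) -> float | None:
    """Empty-mask handling shared by the surface metrics.

    Both masks empty -> 0; exactly one empty -> the spacing-scaled volume
    diagonal (a flagged worst-case value) with a logged warning; otherwise
    None (the metric proper applies).
    """
    ex, ey = bool(np.any(x)), bool(np.any(y))
    if not ex and not ey:
        return 0.0
    if ex != ey:
        shape = np.asarray(x.shape, dtype=np.float64)
        sp = np.asarray(spacing, dtype=np.float64)
        if shape.size == 2:
            sp = sp[-2:]
        worst = float(np.sqrt(((shape * sp) ** 2).sum()))
        logger.warning("%s: exactly one mask is empty; returning the "
                       "worst-case volume diagonal %.3f mm", name, worst)
        return worst
    return None


# ---------------------------------------------------------------------------
# per-case report
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Per-class and mean metrics for one (prediction, truth) volume pair."""

    dsc: dict[int, float]                  # percent
    hd95: dict[int, float]                 # mm; NaN when undefined
    asd: dict[int, float]
    assd: dict[int, float]
    confusion: np.ndarray
    skipped_classes: list[int] = field(default_factory=list)

    def _mean(self, d: dict[int, float]) -> float:
        vals = [v for v in d.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_dsc(self) -> float:
        return self._mean(self.dsc)

    @property
    def mean_hd95(self) -> float:
        return self._mean(self.hd95)

    @property
    def mean_asd(self) -> float:
        return self._mean(self.asd)

    @property
    def mean_assd(self) -> float:
        return self._mean(self.assd)


def evaluate_case(pred: np.ndarray, truth: np.ndarray, spacing,
                  num_classes: int) -> MetricReport:
    """Foreground-class metrics for one volume pair.

    Classes absent from both volumes score DSC 1 / distances 0; classes
    absent from exactly one score DSC 0 and their distances are recorded as
    NaN and excluded from the report means.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    dscs, h95s, asds, assds = {}, {}, {}, {}
    skipped = []
    for k in range(1, num_classes):
        pk = pred == k
        tk = truth == k
        ep, et = bool(pk.any()), bool(tk.any())
        if not ep and not et:
            dscs[k], h95s[k], asds[k], assds[k] = 100.0, 0.0, 0.0, 0.0
            continue
        if ep != et:
            logger.warning(
                "class %d present in only one of prediction/truth; scoring "
                "DSC 0 and excluding it from distance aggregation", k)
            dscs[k] = 0.0
            h95s[k] = asds[k] = assds[k] = float("nan")
            skipped.append(k)
            continue
        dscs[k] = 100.0 * dice_coefficient(pk, tk)
        h95s[k] = hd95(pk, tk, spacing)
        asds[k] = asd(pk, tk, spacing)
        assds[k] = assd(pk, tk, spacing)
    cm = confusion_matrix(pred, truth, num_classes)
    return MetricReport(dsc=dscs, hd95=h95s, asd=asds, assd=assds,
                        confusion=cm, skipped_classes=skipped)
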