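"""Synthetic CT-like phantom volumes with labelled organ-like blobs.

Real abdominal CT with expert annotations cannot ship with a library, so the
training/inference/evaluation pipeline is exercised on phantoms: each
foreground class is an axis-aligned ellipsoid ("organ") of a class-specific
mean intensity placed without overlap in a noisy background, mimicking CT
volumes whose intensities have been windowed and normalised to [0, 1].
Ellipsoids have sharp, analytically known boundaries, which is exactly what
the surface-distance metrics need for testing.

A ``Case`` is the unit of I/O: image volume + integer label volume + voxel
spacing (mm), stored as a NIfTI pair ``<id>_img.nii.gz`` / ``<id>_lab.nii.gz``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize


class GenerationError(RuntimeError):
    pass


class FormatError(ValueError):
    pass


@dataclass
class PhantomSpec:
    n_classes: int = 3
    slice_shape: tuple[int, int] = (64, 64)
    n_slices: int = 4
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_intensity: tuple[float, ...] = (0.10, 0.45, 0.80)
    noise_sd: float = 0.02
    min_blob_radius: int = 6
    max_blob_radius: int = 14
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.class_intensity) != self.n_classes:
            raise ValueError("class_intensity must have one entry per class")
        if len(set(np.round(self.class_intensity, 6))) != self.n_classes:
            raise ValueError("class intensities must be pairwise distinct")
        if not (0 < self.min_blob_radius <= self.max_blob_radius):
            raise ValueError("blob radii must satisfy 0 < min <= max")
        if self.max_blob_radius >= min(self.slice_shape) / 2:
            raise ValueError("max_blob_radius must be < min(slice_shape)/2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class Case:
    image: np.ndarray          # (slice, row, col), float in [0, 1]
    label: np.ndarray          # (slice, row, col), integer class ids
    spacing: tuple[float, float, float]
    case_id: str = "case"

    def validate(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError("image and label shapes differ")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


def tiny_spec(seed: int = 0) -> PhantomSpec:
    """Small fixture preset used throughout the test suite (K=3, 64x64x4)."""
    return PhantomSpec(seed=seed)


def synapse_like_spec(seed: int = 0) -> PhantomSpec:
    """Larger multi-organ phantom: 9 classes on 128x128x8 slabs."""
    intensities = tuple(np.round(np.linspace(0.05, 0.95, 9), 3))
    return PhantomSpec(n_classes=9, slice_shape=(128, 128), n_slices=8,
                       class_intensity=intensities, noise_sd=0.02,
                       min_blob_radius=8, max_blob_radius=20, seed=seed)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    d = ((zz - center[0]) / radii[0]) ** 2 \
        + ((yy - center[1]) / radii[1]) ** 2 \
        + ((xx - center[2]) / radii[2]) ** 2
    return d <= 1.0


def generate_case(spec: PhantomSpec, case_id: str | None = None,
                  max_retries: int = 200) -> Case:
    """Generate one phantom volume; deterministic for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_slices, *spec.slice_shape)
    label = np.zeros(shape, dtype=np.int16)
    occupied = np.zeros(shape, dtype=bool)
    for k in range(1, spec.n_classes):
        placed = False
        for _ in range(max_retries):
            r_yx = rng.integers(spec.min_blob_radius, spec.max_blob_radius + 1,
                                size=2)
            rz = max(1.0, min(spec.n_slices / 2.0 - 0.25, float(r_yx.min()) / 4.0))
            cz = rng.uniform(rz - 0.5, spec.n_slices - rz + 0.5 - 1e-6)
            cy = rng.uniform(r_yx[0], spec.slice_shape[0] - r_yx[0])
            cx = rng.uniform(r_yx[1], spec.slice_shape[1] - r_yx[1])
            mask = _ellipsoid_mask(shape, (cz, cy, cx), (rz, r_yx[0], r_yx[1]))
            if not mask.any():
                continue
            if (mask & occupied).any():
                continue
            label[mask] = k
            occupied |= mask
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place a non-overlapping blob for class {k} after "
                f"{max_retries} retries; reduce blob radii or class count")
    intens = np.asarray(spec.class_intensity, dtype=np.float32)
    image = intens[label]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
        image = np.clip(image, 0.0, 1.0)
    return Case(image=image.astype(np.float32), label=label,
                spacing=tuple(float(s) for s in spec.spacing),
                case_id=case_id or f"phantom{spec.seed:04d}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_case(case: Case, out_dir) -> tuple[Path, Path]:
    case.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(case.spacing)
    img_path = out_dir / f"{case.case_id}_img.nii.gz"
    lab_path = out_dir / f"{case.case_id}_lab.nii.gz"
    nib.save(nib.Nifti1Image(case.image.astype(np.float32), aff), str(img_path))
    nib.save(nib.Nifti1Image(case.label.astype(np.int16), aff), str(lab_path))
    return img_path, lab_path


def read_case(case_dir, case_id: str) -> Case:
    case_dir = Path(case_dir)
    img_nii = nib.load(str(case_dir / f"{case_id}_img.nii.gz"))
    lab_nii = nib.load(str(case_dir / f"{case_id}_lab.nii.gz"))
    image = np.asarray(img_nii.dataobj, dtype=np.float32)
    label_raw = np.asarray(lab_nii.dataobj)
    if not np.allclose(label_raw, np.round(label_raw), atol=1e-6):
        raise FormatError(f"label volume for {case_id!r} has non-integer values")
    label = np.round(label_raw).astype(np.int16)
    if image.shape != label.shape:
        raise FormatError(
            f"{case_id!r}: image shape {image.shape} != label shape {label.shape}")
    sp_img = img_nii.header.get_zooms()[:3]
    sp_lab = lab_nii.header.get_zooms()[:3]
    if not np.allclose(sp_img, sp_lab, atol=1e-6):
        raise FormatError(f"{case_id!r}: image/label spacing mismatch")
    return Case(image=image, label=label,
                spacing=tuple(float(s) for s in sp_img), case_id=case_id)


def list_cases(case_dir) -> list[str]:
    case_dir = Path(case_dir)
    ids = sorted(p.name[:-len("_img.nii.gz")]
                 for p in case_dir.glob("*_img.nii.gz"))
    return [i for i in ids if (case_dir / f"{i}_lab.nii.gz").exists()]


# ---------------------------------------------------------------------------
# slice extraction
# ---------------------------------------------------------------------------


def resize_image2d(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bicubic image resize (values may overshoot slightly; not clipped)."""
    if img.shape == tuple(size):
        return img.astype(np.float32)
    out = _sk_resize(img.astype(np.float64), size, order=3, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def resize_label2d(lab: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour label resize (value set is preserved)."""
    if lab.shape == tuple(size):
        return lab.copy()
    out = _sk_resize(lab, size, order=0, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    return np.round(out).astype(lab.dtype)


def make_training_slices(case: Case, input_size: int):
    """Axial slices resized to the square working resolution.

    Returns a list of (image2d, label2d) with image2d of shape
    (3, input_size, input_size) — the grayscale slice replicated to three
    channels — and integer label2d of shape (input_size, input_size).
    """
    case.validate()
    if case.image.size == 0 or case.image.shape[0] == 0:
        raise ValueError("empty volume")
    out = []
    for s in range(case.image.shape[0]):
        img = resize_image2d(case.image[s], (input_size, input_size))
        lab = resize_label2d(case.label[s], (input_size, input_size))
        out.append((np.repeat(img[None], 3, axis=0), lab))
    return out
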