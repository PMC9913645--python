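"""Lesion-patch preprocessing: ROI extraction, augmentation, cohort splitting.

The model consumes 128x128 single-channel patches centred on the tumour.  The
ROI is supplied by the user (centre + extent, e.g. from a radiologist's
annotation); cropping extends outward from the centre until the window reaches
128 pixels a side, keeps the full tumour when its extent exceeds 128 (and then
downscales), pads by edge replication when the window leaves the scan, and
finally min-max normalises intensities to [0, 1].
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

PATCH_SIZE = 128


# --------------------------------------------------------------------- types
@dataclass
class RoiImage:
    """A preprocessed 128x128 lesion patch with intensities in [0, 1]."""

    pixels: np.ndarray
    source_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"ROI patch must be {PATCH_SIZE}x{PATCH_SIZE}, "
                             f"got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("ROI patch contains NaN/Inf")
        if self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6:
            raise ValueError("ROI patch intensities must lie in [0, 1]")


@dataclass
class SurvivalRecord:
    time: float  # months
    event: int   # 1 = death/relapse observed, 0 = censored

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class LabeledSample:
    image: RoiImage
    patient_id: str
    label: int  # 0 = PD-1-negative, 1 = PD-1-positive
    survival: SurvivalRecord | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class CohortSplit:
    train: list[LabeledSample]
    test: list[LabeledSample]
    seed: int

    def patient_ids(self, cohort: str) -> set[str]:
        samples = self.train if cohort == "train" else self.test
        return {s.patient_id for s in samples}


# ------------------------------------------------------------- preprocessing
def normalize_to_unit(pixels: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max normalise to [0, 1]; constant images map to 0."""
    pixels = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi > lo:
        out = (pixels - lo) / (hi - lo)
    else:
        out = np.zeros_like(pixels)
    return out.astype(np.float32), (lo, hi)


def crop_roi(image: np.ndarray, tumor_center: tuple[int, int],
             tumor_extent: int) -> RoiImage:
    """Extract a tumour-centred square window and resize it to 128x128.

    The window side is ``max(128, tumor_extent)`` so that tumours larger than
    the patch keep their full boundary and are downscaled; windows that
    overhang the scan are padded by edge replication.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("input image must be a non-empty 2-D array")
    h, w = image.shape
    r, c = int(tumor_center[0]), int(tumor_center[1])
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"tumor_center {tumor_center} outside image bounds {image.shape}")
    side = max(PATCH_SIZE, int(tumor_extent))
    r0, c0 = r - side // 2, c - side // 2
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + side - h)
    pad_right = max(0, c0 + side - w)
    if pad_top or pad_left or pad_bottom or pad_right:
        image = np.pad(image, ((pad_top, pad_bottom), (pad_left, pad_right)), mode="edge")
        r0 += pad_top
        c0 += pad_left
    window = image[r0:r0 + side, c0:c0 + side]
    if side != PATCH_SIZE:
        window = _sk_resize(window, (PATCH_SIZE, PATCH_SIZE), order=1,
                            anti_aliasing=side > PATCH_SIZE, preserve_range=True)
    pixels, source_range = normalize_to_unit(window)
    return RoiImage(pixels=pixels, source_range=source_range)


# -------------------------------------------------------------- augmentation
@dataclass
class AugmentConfig:
    """Stochastic augmentation settings; probability 0 disables a transform."""

    flip_prob: float = 0.5
    rotate_prob: float = 0.5
    max_rotation_deg: float = 15.0
    crop_prob: float = 0.5
    crop_scale: tuple[float, float] = (0.8, 1.0)
    jitter_prob: float = 0.5
    brightness_delta: float = 0.2
    contrast_delta: float = 0.2

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(flip_prob=0.0, rotate_prob=0.0, crop_prob=0.0, jitter_prob=0.0)


def rotate_image(pixels: np.ndarray, degrees: float) -> np.ndarray:
    """Bilinear rotation about the patch centre with edge-mode fill."""
    return _sk_rotate(pixels.astype(np.float64), degrees, order=1, mode="edge",
                      preserve_range=True).astype(np.float32)


def augment(sample: LabeledSample, config: AugmentConfig,
            rng: np.random.Generator) -> LabeledSample:
    """Apply spatial and appearance augmentation; label/patient id unchanged.

    With every probability 0 the image is returned bit-identical.
    """
    px = sample.image.pixels
    if rng.random() < config.flip_prob:
        px = px[:, ::-1].copy()
    if config.rotate_prob > 0 and rng.random() < config.rotate_prob:
        deg = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        px = rotate_image(px, deg)
    if config.crop_prob > 0 and rng.random() < config.crop_prob:
        scale = rng.uniform(*config.crop_scale)
        side = max(8, int(round(PATCH_SIZE * scale)))
        r0 = rng.integers(0, PATCH_SIZE - side + 1)
        c0 = rng.integers(0, PATCH_SIZE - side + 1)
        crop = px[r0:r0 + side, c0:c0 + side]
        px = _sk_resize(crop.astype(np.float64), (PATCH_SIZE, PATCH_SIZE), order=1,
                        anti_aliasing=False, preserve_range=True).astype(np.float32)
    if config.jitter_prob > 0 and rng.random() < config.jitter_prob:
        px = px.astype(np.float64)
        px = px + rng.uniform(-config.brightness_delta, config.brightness_delta)
        factor = 1.0 + rng.uniform(-config.contrast_delta, config.contrast_delta)
        px = (px - px.mean()) * factor + px.mean()
        px = px.astype(np.float32)
    px = np.clip(px, 0.0, 1.0)
    image = RoiImage(pixels=px, source_range=sample.image.source_range)
    return replace(sample, image=image)


# ------------------------------------------------------------------ splitting
def holdout_split(samples: list[LabeledSample], ratio: float = 0.8,
                  seed: int = 0) -> CohortSplit:
    """Patient-level hold-out split.

    Patients (not images) are shuffled and the first ``ceil(ratio * n)`` go to
    the training cohort, so 93 patients at 8:2 give 75/18.  No patient ever
    straddles the two cohorts.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = math.ceil(ratio * len(patients))
    train_ids = {patients[i] for i in order[:n_train]}
    train = [s for s in samples if s.patient_id in train_ids]
    test = [s for s in samples if s.patient_id not in train_ids]
    return CohortSplit(train=train, test=test, seed=seed)


# ------------------------------------------------------------------------ IO
def write_cohort(samples: list[LabeledSample], out_dir: str) -> str:
    """Write samples as 16-bit PNGs plus a CSV manifest; returns manifest path."""
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows = []
    counts: dict[str, int] = {}
    for s in samples:
        k = counts.get(s.patient_id, 0)
        counts[s.patient_id] = k + 1
        rel = os.path.join("images", f"{s.patient_id}_{k:03d}.png")
        arr = np.round(s.image.pixels * 65535).astype(np.uint16)
        Image.fromarray(arr).save(os.path.join(out_dir, rel))
        row = {"path": rel, "patient_id": s.patient_id, "label": s.label}
        if s.survival is not None:
            row["time"] = s.survival.time
            row["event"] = s.survival.event
        rows.append(row)
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str) -> list[LabeledSample]:
    """Load a cohort from a CSV manifest (columns: path, patient_id, label,
    optional time/event); image paths are relative to the manifest."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    df = pd.read_csv(manifest_path)
    samples = []
    for row in df.itertuples(index=False):
        arr = np.asarray(Image.open(os.path.join(base, row.path)), dtype=np.float64)
        pixels, rng_ = normalize_to_unit(arr)
        survival = None
        if hasattr(row, "time") and not pd.isna(row.time):
            survival = SurvivalRecord(time=float(row.time), event=int(row.event))
        samples.append(LabeledSample(
            image=RoiImage(pixels=pixels, source_range=rng_),
            patient_id=str(row.patient_id),
            label=int(row.label),
            survival=survival,
        ))
    return samples


def stack_images(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, 1, 128, 128) float32 images and (N,) labels."""
    x = np.stack([s.image.pixels for s in samples])[:, None, :, :].astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.int64)
    return x, y
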