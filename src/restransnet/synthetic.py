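"""Seeded synthetic CT-lesion cohort generator.

Emulates the study data: 128x128 grayscale tumour-centred patches whose
texture differs by PD-1 class, multiple images per patient, a class
prevalence near the clinical one (~21% positive), and optional survival times
whose hazard ratio links to the class.  The class signal is an oriented
band-pass texture confined to a central "tumour" disk and added on top of a
shared smooth parenchyma background plus per-image smooth variation and
pixel noise.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import (
    PATCH_SIZE,
    LabeledSample,
    RoiImage,
    SurvivalRecord,
    normalize_to_unit,
)

# texture geometry (pixels) and intensity scales (normalised units)
_TEMPLATE_RADIUS = 36.0
_TEMPLATE_WAVELENGTH = 8.0
_TEMPLATE_ANGLE_DEG = 30.0
_SIGNAL_AMPLITUDE = 0.1   # per unit effect_size
_BACKGROUND_JITTER = 0.03
_BASELINE_MEDIAN_OS = 33.0  # months, PD-1-negative group
_CENSOR_WINDOW = (6.0, 60.0)  # months, uniform administrative censoring


@dataclass
class SyntheticCohortSpec:
    """Conditions of a simulated cohort.

    survival_link is the hazard ratio of the PD-1-positive class relative to
    the negative class (1.0 = no prognostic difference).
    """

    n_patients: int = 93
    images_per_patient: tuple[int, int] = (2, 6)
    prevalence: float = 0.213
    effect_size: float = 1.0
    noise_sd: float = 0.08
    survival_link: float | None = 1.4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        lo, hi = self.images_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("images_per_patient must be a range with 1 <= lo <= hi")
        if self.survival_link is not None and self.survival_link <= 0:
            raise ValueError("survival_link must be positive")


def _grid():
    r = np.arange(PATCH_SIZE, dtype=np.float64)
    return np.meshgrid(r, r, indexing="ij")


def texture_template(radius: float = _TEMPLATE_RADIUS,
                     center: tuple[float, float] = (64.0, 64.0)) -> np.ndarray:
    """The planted class-discriminative pattern: an oriented sinusoidal
    grating confined to the tumour disk with a cosine edge taper.

    The grating phase is fixed in image coordinates (only the disk mask
    follows the tumour centre), so averaging over patients with jittered
    centres recovers the template instead of washing out its phase.
    """
    rr, cc = _grid()
    theta = np.deg2rad(_TEMPLATE_ANGLE_DEG)
    phase = 2 * np.pi * ((rr - 64.0) * np.cos(theta)
                         + (cc - 64.0) * np.sin(theta)) / _TEMPLATE_WAVELENGTH
    dist = np.hypot(rr - center[0], cc - center[1])
    taper = np.clip((radius + 4.0 - dist) / 8.0, 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * taper)  # smooth 0 -> 1 inside the disk
    return np.sin(phase) * mask


def _shared_background() -> np.ndarray:
    """Smooth parenchyma-like background, identical for every image."""
    rr, cc = _grid()
    rad = np.hypot(rr - 64.0, cc - 64.0) / 90.0
    bg = (0.55
          - 0.12 * rad**2
          + 0.05 * np.sin(2 * np.pi * rr / 96.0)
          + 0.04 * np.cos(2 * np.pi * cc / 72.0))
    return bg


def simulate_survival(labels: np.ndarray, hazard_ratio: float,
                      rng: np.random.Generator,
                      baseline_median: float = _BASELINE_MEDIAN_OS,
                      censor_window: tuple[float, float] = _CENSOR_WINDOW,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with class-linked hazard plus uniform
    administrative censoring; returns (time, event)."""
    labels = np.asarray(labels)
    rate = (np.log(2.0) / baseline_median) * np.where(labels == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(*censor_window, size=labels.shape)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return np.maximum(time, 1e-3), event


def generate_synthetic_cohort(spec: SyntheticCohortSpec) -> list[LabeledSample]:
    """Draw a fully reproducible cohort of labelled lesion patches.

    Patients carry a Bernoulli(prevalence) PD-1 label (at least one patient of
    each class is enforced), a tumour radius and small centre jitter shared by
    their images, and optional survival times.  Class-1 images receive the
    oriented texture scaled by ``0.1 * effect_size``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_patients) < spec.prevalence).astype(int)
    if labels.min() == labels.max():  # degenerate draw: force both classes
        labels[rng.integers(spec.n_patients)] = 1 - labels[0]
    if spec.survival_link is not None:
        times, events = simulate_survival(labels, spec.survival_link, rng)
    background = _shared_background()
    lo, hi = spec.images_per_patient
    samples: list[LabeledSample] = []
    for p in range(spec.n_patients):
        label = int(labels[p])
        radius = rng.uniform(28.0, 44.0)
        center = (64.0 + rng.uniform(-3, 3), 64.0 + rng.uniform(-3, 3))
        template = texture_template(radius=radius, center=center)
        survival = None
        if spec.survival_link is not None:
            survival = SurvivalRecord(time=float(times[p]), event=int(events[p]))
        n_images = int(rng.integers(lo, hi + 1))
        for _ in range(n_images):
            img = background.copy()
            smooth = gaussian_filter(rng.normal(0.0, 1.0, background.shape), sigma=16.0)
            img += smooth / (smooth.std() + 1e-12) * _BACKGROUND_JITTER
            if label == 1:
                img += _SIGNAL_AMPLITUDE * spec.effect_size * template
            img += rng.normal(0.0, spec.noise_sd, background.shape)
            pixels, src = normalize_to_unit(img)
            samples.append(LabeledSample(
                image=RoiImage(pixels=pixels, source_range=src),
                patient_id=f"P{p:04d}",
                label=label,
                survival=survival,
            ))
    return samples
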