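"""Synthetic ROI cohorts with controlled texture irregularity.

The real tumor ROIs this pipeline was designed for are not publicly
available, so this module generates labeled stand-in cohorts with the
statistical structure the analysis assumes:

* two texture classes — a **regular** class (smooth, spatially
  correlated Gaussian field: the low-entropy, ADC-like side) and an
  **irregular** class (weak smooth background plus strong i.i.d. noise:
  the high-entropy, SCC-like side);
* several images per patient, with a per-patient latent field and
  per-patient parameter jitter so that images of one patient are more
  alike than images of different patients (this is what makes
  patient-grouped cross-validation meaningful);
* injected Gaussian and salt-and-pepper noise, so both the normalize
  and the median filtration have something to remove.

Three presets are provided: ``strong`` (classes clearly separated in
the entropy features), ``weak`` (overlapping), and ``null`` (both
classes drawn from identical parameters — no real signal).

Everything is seeded and byte-reproducible: the same config always
yields the same images and manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .images import RoiImage

__all__ = [
    "SyntheticConfig",
    "PRESETS",
    "preset_config",
    "make_regular_roi",
    "make_irregular_roi",
    "inject_noise",
    "generate_cohort",
]

MANIFEST_COLUMNS = ("path", "patient_id", "class_label")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic two-class ROI cohort.

    The default patient counts (12 regular vs 19 irregular) mirror a
    realistic imbalanced clinical cohort; ``images_per_patient`` images
    are generated per patient. Intensities are 8-bit on disk.
    """

    n_patients_regular: int = 12
    n_patients_irregular: int = 19
    images_per_patient: int = 5
    image_size: int = 128
    corr_len_regular: float = 18.0
    noise_sd_regular: float = 6.0
    noise_sd_irregular: float = 45.0
    bg_amplitude_frac: float = 0.1
    bg_corr_len: float = 8.0
    gaussian_sd: float = 4.0
    sp_fraction: float = 0.02
    intensity_range: tuple[float, float] = (0.0, 255.0)
    patient_weight: float = 0.5
    patient_jitter_sd: float = 0.3
    null_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients_regular, self.n_patients_irregular,
               self.images_per_patient) < 0:
            raise ValueError("counts must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if not 0.0 <= self.sp_fraction <= 1.0:
            raise ValueError("sp_fraction must be in [0, 1]")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError("intensity_range must satisfy min < max")
        if self.corr_len_regular <= 0 or self.bg_corr_len <= 0:
            raise ValueError("correlation lengths must be > 0")
        if not 0.0 <= self.patient_weight <= 1.0:
            raise ValueError("patient_weight must be in [0, 1]")


#: Named study conditions. ``strong`` separates the classes clearly in
#: the entropy features; ``weak`` overlaps them; ``null`` uses identical
#: parameters for both classes (pure noise labels).
PRESETS: dict[str, dict] = {
    "strong": {},
    "weak": {"noise_sd_regular": 30.0, "noise_sd_irregular": 45.0,
             "corr_len_regular": 12.0},
    "null": {"null_mode": True},
}


def preset_config(name: str, **overrides) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` for a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def _unit_smooth_field(size: int, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """White noise convolved with an isotropic Gaussian kernel, unit SD."""
    f = gaussian_filter(rng.standard_normal((size, size)), sigma=corr_len, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _structure_amplitude(size: int, corr_len: float, span: float) -> float:
    # correlation lengths approaching the image size fade toward a flat field
    return 0.25 * span * min(1.0, size / (8.0 * corr_len))


def make_regular_roi(
    size: int,
    corr_len: float,
    intensity_range: tuple[float, float] = (0.0, 255.0),
    seed=0,
) -> RoiImage:
    """Smooth, spatially correlated field — the low-entropy texture class.

    White noise is convolved with an isotropic Gaussian low-pass kernel
    of width ``corr_len`` and rescaled into ``intensity_range``; the
    amplitude fades as ``corr_len`` approaches the image size, so very
    long correlation lengths give a near-constant field.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if corr_len <= 0:
        raise ValueError("corr_len must be > 0")
    lo, hi = intensity_range
    if not lo < hi:
        raise ValueError("intensity_range must satisfy min < max")
    rng = np.random.default_rng(seed)
    field = _unit_smooth_field(size, corr_len, rng)
    amp = _structure_amplitude(size, corr_len, hi - lo)
    pixels = np.clip((lo + hi) / 2.0 + amp * field, lo, hi)
    return RoiImage(pixels=pixels, class_label="regular")


def make_irregular_roi(
    size: int,
    noise_sd: float,
    intensity_range: tuple[float, float] = (0.0, 255.0),
    seed=0,
    bg_amplitude_frac: float = 0.1,
    bg_corr_len: float = 8.0,
) -> RoiImage:
    """Weak smooth background plus i.i.d. noise — the high-entropy class."""
    if size < 8:
        raise ValueError("size must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = intensity_range
    if not lo < hi:
        raise ValueError("intensity_range must satisfy min < max")
    rng = np.random.default_rng(seed)
    bg = bg_amplitude_frac * (hi - lo) * _unit_smooth_field(size, bg_corr_len, rng)
    noise = rng.normal(0.0, noise_sd, (size, size)) if noise_sd > 0 else 0.0
    pixels = np.clip((lo + hi) / 2.0 + bg + noise, lo, hi)
    return RoiImage(pixels=pixels, class_label="irregular")


def inject_noise(
    image: RoiImage,
    gaussian_sd: float = 0.0,
    sp_fraction: float = 0.0,
    seed=0,
    intensity_range: tuple[float, float] = (0.0, 255.0),
) -> RoiImage:
    """Add Gaussian noise, then salt-and-pepper corruption.

    A seeded random subset of pixels (expected fraction ``sp_fraction``)
    is replaced by the intensity minimum or maximum with equal
    probability; the result is clipped into ``intensity_range``.
    """
    if gaussian_sd < 0:
        raise ValueError("gaussian_sd must be >= 0")
    if not 0.0 <= sp_fraction <= 1.0:
        raise ValueError("sp_fraction must be in [0, 1]")
    if gaussian_sd == 0.0 and sp_fraction == 0.0:
        return image
    lo, hi = intensity_range
    rng = np.random.default_rng(seed)
    x = image.pixels.copy()
    if gaussian_sd > 0:
        x = x + rng.normal(0.0, gaussian_sd, x.shape)
    if sp_fraction > 0:
        corrupt = rng.random(x.shape) < sp_fraction
        salt = rng.random(x.shape) < 0.5
        x = np.where(corrupt, np.where(salt, hi, lo), x)
    return image.with_pixels(np.clip(x, lo, hi))


def _cohort_image(
    cfg: SyntheticConfig,
    class_label: str,
    latent: np.ndarray,
    corr_len: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One cohort image: latent/individual structure mix plus class noise."""
    lo, hi = cfg.intensity_range
    span = hi - lo
    size = cfg.image_size
    irregular_process = class_label == "irregular" or cfg.null_mode
    if irregular_process:
        struct_corr, amp = cfg.bg_corr_len, cfg.bg_amplitude_frac * span
    else:
        struct_corr = corr_len
        amp = _structure_amplitude(size, corr_len, span)
    indiv = _unit_smooth_field(size, struct_corr, rng)
    w = cfg.patient_weight
    mix = w * latent + (1.0 - w) * indiv
    msd = mix.std()
    if msd > 0:
        mix = mix / msd
    x = (lo + hi) / 2.0 + amp * mix
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.shape)
    return np.clip(x, lo, hi)


def generate_cohort(config: SyntheticConfig) -> tuple[list[RoiImage], pd.DataFrame]:
    """Generate the full labeled cohort and its manifest.

    Returns the list of 8-bit-valued :class:`RoiImage` (pixels rounded
    to integers, as they would be after a BMP round trip) and a manifest
    with one row per image: ``path`` (the file name the image would be
    written to), ``patient_id`` and ``class_label``. Patient identifiers
    never overlap between classes.
    """
    images: list[RoiImage] = []
    rows: list[dict] = []
    class_plan = [
        ("regular", "REG", 0, config.n_patients_regular,
         config.corr_len_regular, config.noise_sd_regular),
        ("irregular", "IRR", 1, config.n_patients_irregular,
         config.bg_corr_len, config.noise_sd_irregular),
    ]
    if config.null_mode:
        # both classes drawn from the irregular process with identical params
        class_plan = [
            ("regular", "REG", 0, config.n_patients_regular,
             config.bg_corr_len, config.noise_sd_irregular),
            ("irregular", "IRR", 1, config.n_patients_irregular,
             config.bg_corr_len, config.noise_sd_irregular),
        ]
    for class_label, prefix, class_idx, n_pat, corr_len, noise_sd in class_plan:
        for p in range(n_pat):
            patient_id = f"{prefix}{p + 1:03d}"
            prng = np.random.default_rng([config.seed, class_idx, p])
            jit_corr = corr_len * float(
                np.exp(prng.normal(0.0, config.patient_jitter_sd))
            )
            jit_noise = noise_sd * float(
                np.exp(prng.normal(0.0, config.patient_jitter_sd))
            )
            latent_corr = (
                config.bg_corr_len
                if (class_label == "irregular" or config.null_mode)
                else jit_corr
            )
            latent = _unit_smooth_field(config.image_size, latent_corr, prng)
            for j in range(config.images_per_patient):
                irng = np.random.default_rng([config.seed, class_idx, p, j])
                x = _cohort_image(
                    config, class_label, latent, jit_corr, jit_noise, irng
                )
                img = RoiImage(
                    pixels=x, patient_id=patient_id, class_label=class_label
                )
                img = inject_noise(
                    img,
                    gaussian_sd=config.gaussian_sd,
                    sp_fraction=config.sp_fraction,
                    seed=[config.seed, class_idx, p, j, 1],
                    intensity_range=config.intensity_range,
                )
                # emulate the 8-bit on-disk representation
                lo, hi = config.intensity_range
                pixels = np.clip(np.rint(img.pixels), lo, hi)
                img = img.with_pixels(pixels)
                images.append(img)
                rows.append(
                    {
                        "path": f"{patient_id}_img{j + 1:02d}.bmp",
                        "patient_id": patient_id,
                        "class_label": class_label,
                    }
                )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return images, manifest
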