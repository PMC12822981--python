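"""Region-of-interest image container.

A :class:`RoiImage` is a rectangular 2D grayscale intensity array together
with the metadata the analysis pipeline needs to keep track of: which
patient the ROI was cut from, which diagnostic class the patient belongs
to, and which preprocessing stage produced the pixels (``raw``,
``normalize`` or ``median``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["RoiImage", "IMAGE_TYPES"]

IMAGE_TYPES = ("raw", "normalize", "median")


@dataclass(frozen=True)
class RoiImage:
    """A 2D grayscale ROI with provenance metadata.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Finite real intensities. On disk ROIs are 8-bit (0..255) but after
        filtration pixels may take any finite real value.
    patient_id : str, optional
        Identifier of the patient the ROI belongs to. All images of one
        patient share it; grouped cross-validation splits on it.
    class_label : str, optional
        Diagnostic class of the patient (e.g. ``"regular"`` / ``"irregular"``
        for the synthetic cohorts, mirroring the ADC/SCC dichotomy).
    image_type : str
        Which preprocessing produced the pixels: ``raw``, ``normalize``
        or ``median``.
    """

    pixels: np.ndarray
    patient_id: Optional[str] = None
    class_label: Optional[str] = None
    image_type: str = "raw"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("RoiImage requires a non-empty 2D pixel array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("RoiImage pixels must be finite")
        if self.image_type not in IMAGE_TYPES:
            raise ValueError(
                f"image_type must be one of {IMAGE_TYPES}, got {self.image_type!r}"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, image_type: Optional[str] = None) -> "RoiImage":
        """Return a copy with new pixels (and optionally a new image_type)."""
        return replace(
            self, pixels=pixels, image_type=image_type or self.image_type
        )


def as_pixel_array(image) -> np.ndarray:
    """Accept either a RoiImage or a bare 2D array and return float pixels."""
    if isinstance(image, RoiImage):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pixel values must be finite")
    return arr
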