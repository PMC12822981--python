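"""ROI filtrations applied before feature extraction.

Two filters are supported, mirroring common MRI preprocessing practice:

* **normalize** — linear rescaling so the pixel population has zero mean
  and unit variance (contrast normalization; counters Gaussian
  intensity noise);
* **median** — each pixel replaced by the median of its square
  neighborhood (edge-preserving; removes salt-and-pepper outliers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.ndimage import median_filter as _nd_median
from sklearn.base import BaseEstimator, TransformerMixin

from .images import RoiImage, as_pixel_array

__all__ = [
    "FilterSpec",
    "normalize_filter",
    "median_filter",
    "apply_filter",
    "RoiFilter",
]

logger = logging.getLogger(__name__)

FILTER_KINDS = ("none", "normalize", "median")


@dataclass(frozen=True)
class FilterSpec:
    """Which filtration to apply and with what window.

    ``median_radius`` is in pixels: radius 1 means a 3x3 window.
    """

    kind: str = "none"
    median_radius: int = 1

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"kind must be one of {FILTER_KINDS}")
        if self.median_radius < 1:
            raise ValueError("median_radius must be >= 1")


def normalize_filter(image):
    """Rescale pixels to zero mean and unit (population) variance.

    A constant image has no defined rescaling and maps to all zeros
    (with a warning). Returns the same type as the input (RoiImage in,
    RoiImage out with ``image_type='normalize'``; array in, array out).
    """
    x = as_pixel_array(image)
    if x.size < 2:
        raise ValueError("normalize filtration needs at least 2 pixels")
    sd = float(x.std())
    if sd == 0.0:
        logger.warning("normalize filtration of a constant image -> all zeros")
        out = np.zeros_like(x)
    else:
        out = (x - x.mean()) / sd
    if isinstance(image, RoiImage):
        return image.with_pixels(out, image_type="normalize")
    return out


def median_filter(image, radius: int = 1):
    """Replace each pixel by the median of its (2*radius+1)^2 neighborhood.

    The border is replicate-padded, so output values are always drawn
    from the input's value set.
    """
    radius = int(radius)
    if radius < 1:
        raise ValueError("median radius must be >= 1")
    x = as_pixel_array(image)
    out = _nd_median(x, size=2 * radius + 1, mode="nearest")
    if isinstance(image, RoiImage):
        return image.with_pixels(out, image_type="median")
    return out


def apply_filter(image, spec: FilterSpec):
    """Dispatch on :class:`FilterSpec`; ``kind='none'`` passes through."""
    if spec.kind == "normalize":
        return normalize_filter(image)
    if spec.kind == "median":
        return median_filter(image, spec.median_radius)
    return image


class RoiFilter(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying one filtration to each image.

    ``transform`` maps a sequence of images to the list of filtered
    images; stateless, so safe inside cross-validation pipelines.
    """

    def __init__(self, kind: str = "none", median_radius: int = 1) -> None:
        self.kind = kind
        self.median_radius = median_radius

    def fit(self, X: Iterable = (), y=None) -> "RoiFilter":
        self.spec_ = FilterSpec(kind=self.kind, median_radius=self.median_radius)
        return self

    def transform(self, X: Iterable) -> list:
        if not hasattr(self, "spec_"):
            self.fit()
        return [apply_filter(img, self.spec_) for img in X]
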