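"""Assembly of per-image feature tables.

Three feature sets are supported, mirroring the three datasets the
analysis compares:

* ``statistical`` — 17 FOS + 73 SOS features (90 columns);
* ``entropy`` — 5 entropy methods x 5 scales (25 columns);
* ``combined`` — the union (115 columns).

Tables are tidy DataFrames: one row per image, metadata columns
``patient_id``, ``class_label``, ``image_type`` first, then the named
feature columns in a stable order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .entropy import EntropyFeatureExtractor, EntropyParams
from .images import RoiImage
from .radiomics import RadiomicFeatureExtractor

__all__ = ["FEATURE_SETS", "METADATA_COLUMNS", "feature_table", "feature_columns"]

FEATURE_SETS = ("statistical", "entropy", "combined")
METADATA_COLUMNS = ("patient_id", "class_label", "image_type")


def _metadata_frame(images: Sequence[RoiImage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [getattr(img, "patient_id", None) for img in images],
            "class_label": [getattr(img, "class_label", None) for img in images],
            "image_type": [getattr(img, "image_type", "raw") for img in images],
        }
    )


def feature_table(
    images: Sequence[RoiImage],
    feature_set: str = "combined",
    entropy_params: EntropyParams | None = None,
    n_levels: int = 32,
    glcm_distance: int = 1,
    gldm_alpha: float = 0.0,
) -> pd.DataFrame:
    """Extract the requested feature set for every image.

    Returns a DataFrame with the three metadata columns followed by the
    feature columns of the set (90 / 25 / 115 for statistical / entropy
    / combined).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    images = list(images)
    parts = [_metadata_frame(images)]
    if feature_set in ("statistical", "combined"):
        ext = RadiomicFeatureExtractor(
            n_levels=n_levels, glcm_distance=glcm_distance, gldm_alpha=gldm_alpha
        ).fit()
        parts.append(
            pd.DataFrame(ext.transform(images), columns=ext.get_feature_names_out())
        )
    if feature_set in ("entropy", "combined"):
        ep = entropy_params or EntropyParams()
        ext = EntropyFeatureExtractor(
            m_match=ep.m_match,
            m_pattern=ep.m_pattern,
            r_factor=ep.r_factor,
            fuzzy_n=ep.fuzzy_n,
            n_classes=ep.n_classes,
            n_bins=ep.n_bins,
            scales=ep.scales,
        ).fit()
        parts.append(
            pd.DataFrame(ext.transform(images), columns=ext.get_feature_names_out())
        )
    out = pd.concat(parts, axis=1)
    out.index = pd.RangeIndex(len(images))
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything but the metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]
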