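"""Cohort and table I/O.

ROIs travel as 8-bit grayscale images (BMP primary; PNG/TIFF accepted
on read) plus a manifest CSV with columns ``path, patient_id,
class_label`` — one row per image. All tabular artifacts are CSV for
inspectability; every run writes a JSON run manifest echoing the
configuration and seeds.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .images import RoiImage
from .synthetic import MANIFEST_COLUMNS

__all__ = [
    "write_cohort",
    "load_cohort",
    "save_feature_table",
    "save_run_manifest",
]

_GRAYSCALE_MODES = ("L", "I", "I;16")


def write_cohort(
    images: Sequence[RoiImage], manifest: pd.DataFrame, out_dir
) -> Path:
    """Write 8-bit grayscale images and the manifest CSV to ``out_dir``.

    Image file names come from the manifest's ``path`` column; pixel
    values are clipped into 0..255 and rounded. Returns the manifest
    path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(images) != len(manifest):
        raise ValueError("manifest row count must equal the number of images")
    for img, (_, row) in zip(images, manifest.iterrows()):
        arr = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / row["path"])
    manifest_path = out_dir / "manifest.csv"
    manifest[list(MANIFEST_COLUMNS)].to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(manifest_path) -> tuple[list[RoiImage], pd.DataFrame]:
    """Read a manifest CSV and all the images it lists.

    Images must be single-channel grayscale; color files are rejected
    with the offending file named.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    base = manifest_path.parent
    images = []
    for _, row in manifest.iterrows():
        path = base / row["path"]
        if not path.exists():
            raise FileNotFoundError(f"manifest lists missing file: {path}")
        with Image.open(path) as im:
            if im.mode not in _GRAYSCALE_MODES:
                raise ValueError(
                    f"{path.name}: expected 8-bit grayscale, got mode {im.mode!r}"
                )
            arr = np.asarray(im, dtype=float)
        images.append(
            RoiImage(
                pixels=arr,
                patient_id=row["patient_id"],
                class_label=row["class_label"],
            )
        )
    return images, manifest


def save_feature_table(table: pd.DataFrame, path) -> Path:
    """Write a feature table CSV at full floating-point precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def save_run_manifest(config: dict, path) -> Path:
    """Write the run manifest: config echo, seeds, package version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = _pkg_version("texent")
    except PackageNotFoundError:  # editable checkout without metadata
        pkg_version = "unknown"
    payload = {"package": "texent", "version": pkg_version, "config": config}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
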