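"""Reading images and feature tables; writing feature CSVs and sidecars.

Feature tables are plain CSV with columns ``id, label, f1..f768, h1..h7``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .evaluate import LabeledDataset
from .features import feature_names

__all__ = [
    "load_image",
    "iter_image_files",
    "load_labels",
    "write_features_csv",
    "read_features_csv",
]

IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as H×W×3 uint8 RGB.

    Grayscale and RGBA inputs are converted; 16-bit rasters are rescaled
    to the [0, 255] range.
    """
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B"):
            arr = np.asarray(im, dtype=np.float64)
            arr = arr / 65535.0 * 255.0
            arr = np.clip(arr, 0, 255).astype(np.uint8)
            im = Image.fromarray(arr)
        arr = np.asarray(im.convert("RGB"))
    return arr


def iter_image_files(directory: str | Path):
    """Image files directly under (or one level below) a directory, sorted."""
    directory = Path(directory)
    files = [p for p in sorted(directory.rglob("*")) if p.suffix.lower() in IMAGE_SUFFIXES]
    if not files:
        raise FileNotFoundError(f"no image files found under {directory}")
    return files


def load_labels(manifest: str | Path) -> dict:
    """id → label mapping from a manifest CSV with ``id`` and ``label`` columns."""
    df = pd.read_csv(manifest)
    if not {"id", "label"}.issubset(df.columns):
        raise ValueError("manifest must have 'id' and 'label' columns")
    return dict(zip(df["id"].astype(str), df["label"].astype(str)))


def write_features_csv(path: str | Path, ids, labels, X: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(X), columns=feature_names())
    df.insert(0, "label", list(labels))
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path)
    cols = feature_names()
    missing = [c for c in ("id", "label", *cols) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing[:5]} ...")
    return LabeledDataset(
        X=df[cols].to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=str),
        ids=df["id"].to_numpy(dtype=str),
    )
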