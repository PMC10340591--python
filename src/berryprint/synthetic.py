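"""Synthetic single-fruit image generator.

Real origin-labelled fruit photographs are rarely shareable, so this module
renders labelled stand-ins: one elliptical "fruit" per image on a noisy
near-white background, with class identity encoded in the ridge texture
(wavelength, orientation, contrast of a sinusoidal darkening pattern), the
ellipse geometry (major-axis length, aspect ratio) and the base color.
The texture model is deliberately the simplest structure a single Gabor
filter per channel can discriminate; it exercises feature sensitivity, not
photo-realism.  Ground truth (mask, bounding box) is returned for testing
the preprocessing stage.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CropBox

__all__ = [
    "ClassRecipe",
    "GroundTruth",
    "DEFAULT_RECIPES",
    "identical_recipes",
    "generate_image",
    "generate_dataset",
    "SyntheticDataset",
]


@dataclass(frozen=True)
class ClassRecipe:
    """Rendering parameters for one fruit class.

    mean_diameter is the major-axis length in pixels; axis_ratio = a/b ≥ 1
    the ellipse elongation; ridge_* describe the sinusoidal surface texture
    (wavelength in px, orientation in radians, contrast in [0, 1], the
    fractional darkening at ridge troughs); noise_sd is the per-pixel
    Gaussian noise on the fruit, in gray levels.
    """

    name: str
    axis_ratio: float = 1.4
    mean_diameter: float = 64.0
    ridge_wavelength: float = 8.0
    ridge_orientation: float = 0.0
    ridge_contrast: float = 0.5
    base_color: tuple = (190, 60, 45)
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.mean_diameter < 32:
            raise ValueError("mean_diameter must be >= 32 px")
        if self.ridge_wavelength < 2:
            raise ValueError("ridge_wavelength must be >= 2 px")
        if not 0.0 <= self.ridge_contrast <= 1.0:
            raise ValueError("ridge_contrast must lie in [0, 1]")
        if self.axis_ratio < 1.0:
            raise ValueError("axis_ratio must be >= 1")


@dataclass
class GroundTruth:
    """What the renderer knows exactly: object mask and bounding box."""

    mask: np.ndarray  # H×W uint8, 1 on the ellipse
    bbox: CropBox
    area: int  # pixel count of the mask
    analytic_area: float  # π·a·b of the rendered ellipse


#: Two "rugged" classes (short-wavelength, high-contrast ridges) and two
#: "delicate" ones (long-wavelength, low-contrast), with distinct shapes
#: and base colors, mirroring a four-origin study design.
DEFAULT_RECIPES = (
    ClassRecipe(
        "NM", axis_ratio=1.25, mean_diameter=76, ridge_wavelength=8,
        ridge_orientation=math.pi / 4, ridge_contrast=0.65,
        base_color=(178, 52, 40), noise_sd=5,
    ),
    ClassRecipe(
        "QH", axis_ratio=1.75, mean_diameter=68, ridge_wavelength=8,
        ridge_orientation=math.pi / 12, ridge_contrast=0.55,
        base_color=(196, 74, 52), noise_sd=5,
    ),
    ClassRecipe(
        "GS", axis_ratio=1.45, mean_diameter=60, ridge_wavelength=20,
        ridge_orientation=math.pi / 3, ridge_contrast=0.22,
        base_color=(160, 60, 64), noise_sd=5,
    ),
    ClassRecipe(
        "NX", axis_ratio=1.10, mean_diameter=54, ridge_wavelength=20,
        ridge_orientation=2 * math.pi / 3, ridge_contrast=0.18,
        base_color=(204, 92, 60), noise_sd=5,
    ),
)


def identical_recipes(template: ClassRecipe | None = None) -> tuple:
    """Four recipes that differ only in name — a deliberately unlearnable
    class structure used to verify that evaluation shows chance accuracy
    (i.e. no label leakage)."""
    base = template or DEFAULT_RECIPES[0]
    return tuple(replace(base, name=n) for n in ("A", "B", "C", "D"))


def generate_image(
    recipe: ClassRecipe,
    seed: int,
    canvas: tuple = (128, 128),
) -> tuple[np.ndarray, GroundTruth]:
    """Render one fruit image plus its ground truth.

    The ellipse's size (±10%), in-plane rotation, ridge phase and position
    are jittered deterministically from the seed.  Background pixels are
    near-white (≈245–255) with slight noise so thresholding sees a
    realistic bimodal histogram.
    """
    rng = np.random.default_rng(seed)
    h, w = canvas

    a = 0.5 * recipe.mean_diameter * rng.uniform(0.9, 1.1)  # semi-major
    b = a / recipe.axis_ratio  # semi-minor
    margin = 4.0
    if 2 * a + 2 * margin > min(h, w):
        raise ValueError(
            f"ellipse (major axis {2 * a:.0f}px) plus margin does not fit canvas {canvas}"
        )
    rot = rng.uniform(0.0, math.pi)
    slack = 0.5 * min(h, w) - a - margin
    cy = h / 2.0 + rng.uniform(-slack, slack)
    cx = w / 2.0 + rng.uniform(-slack, slack)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy
    cr, sr = math.cos(rot), math.sin(rot)
    u = dx * cr + dy * sr
    v = -dx * sr + dy * cr
    mask = (u**2 / a**2 + v**2 / b**2) <= 1.0

    # sinusoidal ridge field: darkening factor in [1 - contrast, 1]
    co, so = math.cos(recipe.ridge_orientation), math.sin(recipe.ridge_orientation)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    ridge = np.sin(2.0 * math.pi * (xx * co + yy * so) / recipe.ridge_wavelength + phase)
    factor = 1.0 - recipe.ridge_contrast * (0.5 + 0.5 * ridge)

    img = 250.0 + rng.normal(0.0, 2.0, size=(h, w, 3))  # near-white background
    color = np.asarray(recipe.base_color, dtype=float)
    fruit = factor[..., None] * color[None, None, :]
    if recipe.noise_sd > 0:
        fruit = fruit + rng.normal(0.0, recipe.noise_sd, size=fruit.shape)
    img = np.where(mask[..., None], fruit, img)
    img = np.clip(img, 0, 255).astype(np.uint8)

    ys, xs = np.nonzero(mask)
    bbox = CropBox(xmin=int(xs.min()), xmax=int(xs.max()), ymin=int(ys.min()), ymax=int(ys.max()))
    gt = GroundTruth(
        mask=mask.astype(np.uint8),
        bbox=bbox,
        area=int(mask.sum()),
        analytic_area=math.pi * a * b,
    )
    return img, gt


@dataclass
class SyntheticDataset:
    """In-memory rendered dataset: images, labels, ids and ground truth."""

    images: list
    labels: list
    ids: list
    truths: list
    manifest: pd.DataFrame


def generate_dataset(
    recipes: tuple = DEFAULT_RECIPES,
    per_class: int = 90,
    seed: int = 0,
    canvas: tuple = (128, 128),
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Render ``per_class`` images for each recipe.

    Per-image seeds are spawned deterministically from the master seed.
    With ``out_dir`` the images are also written as PNGs next to a
    ``manifest.csv`` (id, label, seed, ground-truth bbox/area) and a
    ``recipes.yaml`` recording the parameters used.
    """
    names = [r.name for r in recipes]
    if len(set(names)) != len(names):
        raise ValueError("recipe names must be distinct")

    children = np.random.SeedSequence(seed).spawn(len(recipes) * per_class)
    images, labels, ids, truths, rows = [], [], [], [], []
    idx = 0
    for recipe in recipes:
        for j in range(per_class):
            img_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            img, gt = generate_image(recipe, img_seed, canvas)
            sample_id = f"{recipe.name}-{j + 1:03d}"
            images.append(img)
            labels.append(recipe.name)
            ids.append(sample_id)
            truths.append(gt)
            rows.append(
                {
                    "id": sample_id,
                    "label": recipe.name,
                    "seed": img_seed,
                    "xmin": gt.bbox.xmin,
                    "xmax": gt.bbox.xmax,
                    "ymin": gt.bbox.ymin,
                    "ymax": gt.bbox.ymax,
                    "area": gt.area,
                }
            )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from PIL import Image
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample_id, img in zip(ids, images):
            Image.fromarray(img).save(out / f"{sample_id}.png")
        manifest_disk = manifest.copy()
        manifest_disk["filename"] = [f"{s}.png" for s in ids]
        manifest_disk.to_csv(out / "manifest.csv", index=False)
        with open(out / "recipes.yaml", "w") as fh:
            yaml.safe_dump([asdict(r) for r in recipes], fh, sort_keys=False)

    return SyntheticDataset(images=images, labels=labels, ids=ids, truths=truths, manifest=manifest)
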