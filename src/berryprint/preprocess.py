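"""Image preprocessing: grayscale conversion, Otsu thresholding, Sobel edge
detection, noise-tolerant cropping and background unification.

The pipeline turns a raw photograph of a single fruit on a light background
into a tightly cropped image in which every background pixel is exactly
black, so that downstream texture and shape features see only the fruit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GRAY_COEFFS",
    "GRAY_COEFFS_LEGACY",
    "SOBEL_GX",
    "SOBEL_GY",
    "CropBox",
    "PreprocessResult",
    "NoObjectFoundError",
    "to_grayscale",
    "otsu_threshold",
    "binarize",
    "sobel_edges",
    "crop_bounds",
    "unify_background",
    "preprocess_image",
]

#: ITU-R BT.601 luma weights (default).
GRAY_COEFFS = (0.299, 0.587, 0.114)
#: Non-standard triple (green weight 0.578, sum 0.991) found in some legacy
#: scripts; kept selectable for bit-faithful replication of such runs.
GRAY_COEFFS_LEGACY = (0.299, 0.578, 0.114)

#: Horizontal / vertical Sobel kernels, applied by correlation.
SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_GY = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


class NoObjectFoundError(ValueError):
    """Raised when an image contains no detectable foreground object."""


@dataclass(frozen=True)
class CropBox:
    """Inclusive, 0-based bounding box (xmin..xmax columns, ymin..ymax rows)."""

    xmin: int
    xmax: int
    ymin: int
    ymax: int

    def __post_init__(self) -> None:
        if not (0 <= self.xmin <= self.xmax and 0 <= self.ymin <= self.ymax):
            raise ValueError(f"invalid crop box {self}")

    @property
    def width(self) -> int:
        return self.xmax - self.xmin + 1

    @property
    def height(self) -> int:
        return self.ymax - self.ymin + 1

    def crop(self, img: np.ndarray) -> np.ndarray:
        """Extract the boxed region of a 2-D or 3-D raster."""
        return img[self.ymin : self.ymax + 1, self.xmin : self.xmax + 1]


@dataclass
class PreprocessResult:
    """Preprocessed image plus the quantities the pipeline derived."""

    image: np.ndarray  # cropped RGB, background exactly (0,0,0)
    crop_box: CropBox
    threshold: int  # selected Otsu gray level
    separability: float  # between/global variance ratio at the threshold
    mask_area: int  # foreground pixel count after morphological cleanup

    def to_dict(self) -> dict:
        b = self.crop_box
        return {
            "crop_box": {"xmin": b.xmin, "xmax": b.xmax, "ymin": b.ymin, "ymax": b.ymax},
            "otsu_threshold": int(self.threshold),
            "separability": float(self.separability),
            "mask_area": int(self.mask_area),
        }


def _require_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    return img


def to_grayscale(img: np.ndarray, coeffs: tuple = GRAY_COEFFS) -> np.ndarray:
    """Weighted-channel grayscale: ``c_R·R + c_G·G + c_B·B``, unclipped.

    Parameters
    ----------
    img : H×W×3 array with channel values in [0, 255].
    coeffs : non-negative weights for (R, G, B).
    """
    img = _require_rgb(img).astype(float)
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (3,) or (c < 0).any():
        raise ValueError("coeffs must be three non-negative reals")
    return img @ c


def otsu_threshold(img: np.ndarray, levels: int = 256) -> tuple[int, float]:
    """Gray threshold maximizing the between/global variance ratio.

    Pixels are quantized to ``levels`` bins; the between-class variance
    σ_B²(k) = P1·(m1−mG)² + P2·(m2−mG)² is evaluated for every candidate
    level k and the argmax returned (ties broken toward the smallest k),
    together with the separability η = σ_B²(k*)/σ_G² ∈ [0, 1].

    Raises
    ------
    ValueError
        If the quantized image is constant ("no threshold exists").
    """
    g = np.asarray(img, dtype=float)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = np.clip(np.floor(g / 256.0 * levels), 0, levels - 1).astype(np.int64)
    hist = np.bincount(q.ravel(), minlength=levels).astype(float)
    n = hist.sum()
    p = hist / n
    lev = np.arange(levels, dtype=float)

    mg = float(lev @ p)
    sigma_g2 = float(((lev - mg) ** 2) @ p)
    if sigma_g2 == 0.0:
        raise ValueError("no threshold exists: image is constant")

    p1 = np.cumsum(p)  # P1(k) for k = 0..L-1
    cummean = np.cumsum(lev * p)  # Σ_{i<=k} i·p_i
    p2 = 1.0 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(p1 > 0, cummean / p1, 0.0)
        m2 = np.where(p2 > 0, (mg - cummean) / p2, 0.0)
    sigma_b2 = p1 * (m1 - mg) ** 2 + p2 * (m2 - mg) ** 2
    sigma_b2[(p1 == 0) | (p2 == 0)] = 0.0

    k_star = int(np.argmax(sigma_b2))  # argmax keeps smallest index on ties
    eta = float(sigma_b2[k_star] / sigma_g2)
    return k_star, eta


def binarize(img: np.ndarray, k: int) -> np.ndarray:
    """Binary mask with 1 where ``pixel > k`` (strict-greater convention)."""
    if not 0 <= k <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return (np.asarray(img, dtype=float) > k).astype(np.uint8)


def sobel_edges(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude ``sqrt(Gx² + Gy²)`` with replicate padding.

    Output has the same shape as the input so edge coordinates stay aligned
    with the source raster.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("sobel_edges expects a 2-D raster")
    gx = ndimage.correlate(a, SOBEL_GX, mode="nearest")
    gy = ndimage.correlate(a, SOBEL_GY, mode="nearest")
    return np.hypot(gx, gy)


def _main_run(coords: np.ndarray, gap_thresh: int) -> tuple[int, int]:
    """Extent of the largest run of coordinates with consecutive gaps <= gap_thresh."""
    splits = np.flatnonzero(np.diff(coords) > gap_thresh)
    runs = np.split(coords, splits + 1)
    best = max(runs, key=len)  # ties resolve to the first (leftmost) run
    return int(best[0]), int(best[-1])


def crop_bounds(edges: np.ndarray, gap_thresh: int = 10) -> CropBox:
    """Bounding box of the main coherent block of nonzero edge responses.

    Nonzero columns (and, independently, rows) are grouped into runs whose
    consecutive coordinates are at most ``gap_thresh`` apart; coordinates
    outside the largest run are treated as isolated noise and discarded.
    """
    e = np.asarray(edges)
    cols = np.flatnonzero((e > 0).any(axis=0))
    rows = np.flatnonzero((e > 0).any(axis=1))
    if cols.size == 0:
        raise NoObjectFoundError("no object found: edge image is empty")
    xmin, xmax = _main_run(cols, gap_thresh)
    ymin, ymax = _main_run(rows, gap_thresh)
    return CropBox(xmin=xmin, xmax=xmax, ymin=ymin, ymax=ymax)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def clean_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing then opening with a disk structuring element.

    The mask is edge-padded before the operations so that foreground touching
    the image border is not eroded away.
    """
    m = np.asarray(mask).astype(bool)
    if radius <= 0:
        return m.astype(np.uint8)
    se = _disk(radius)
    pad = 2 * radius  # erosion border artifacts reach one radius into the padding
    padded = np.pad(m, pad, mode="edge")
    closed = ndimage.binary_closing(padded, structure=se)
    opened = ndimage.binary_opening(closed, structure=se)
    return opened[pad:-pad, pad:-pad].astype(np.uint8)


def unify_background(img: np.ndarray, mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Blacken everything outside the (morphologically cleaned) object mask.

    The mask is closed then opened with a disk of the given radius to fill
    small holes and remove speckle; pixels where the cleaned mask is 0 are
    set to exactly (0, 0, 0) and object pixels pass through unchanged.
    """
    img = _require_rgb(img)
    mask = np.asarray(mask)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.shape[:2]}"
        )
    cleaned = clean_mask(mask, radius)
    out = img.copy()
    out[cleaned == 0] = 0
    return out


def preprocess_image(
    img: np.ndarray,
    *,
    coeffs: tuple = GRAY_COEFFS,
    gap_thresh: int = 10,
    morph_radius: int = 3,
    sobel_on: str = "binary",
    return_info: bool = False,
):
    """Full preprocessing chain for a single-fruit photograph.

    grayscale → Otsu threshold → binarize → Sobel edges → noise-tolerant
    crop → morphological background cleanup.  The returned image is cropped
    to the object's bounding box with the background exactly black.

    The foreground class is chosen as the Otsu class occupying less of the
    image border (the background is assumed to touch the border), so both
    light-background raw photos and already-processed black-background
    images are handled.

    Parameters
    ----------
    sobel_on : ``"binary"`` (default) applies the edge detector to the
        thresholded mask; ``"gray"`` applies it to the grayscale image.
    return_info : if True, return a :class:`PreprocessResult` instead of
        just the image.
    """
    img = _require_rgb(img)
    gray = to_grayscale(img, coeffs)
    try:
        k, eta = otsu_threshold(gray)
    except ValueError as exc:
        raise NoObjectFoundError(f"no object found: {exc}") from exc
    # threshold the quantized gray so pixels at level k fall on the dark side,
    # consistent with the histogram the threshold was selected on
    bw = binarize(np.floor(gray), k)

    border = np.concatenate([bw[0, :], bw[-1, :], bw[1:-1, 0], bw[1:-1, -1]])
    fruit = (1 - bw) if border.mean() > 0.5 else bw

    if sobel_on == "binary":
        edges = sobel_edges(bw.astype(float))
    elif sobel_on == "gray":
        edges = sobel_edges(gray)
    else:
        raise ValueError("sobel_on must be 'binary' or 'gray'")

    box = crop_bounds(edges, gap_thresh)
    cropped = box.crop(img)
    cropped_mask = box.crop(fruit)
    cleaned = clean_mask(cropped_mask, morph_radius)
    out = cropped.copy()
    out[cleaned == 0] = 0

    if return_info:
        return PreprocessResult(
            image=out,
            crop_box=box,
            threshold=k,
            separability=eta,
            mask_area=int(cleaned.sum()),
        )
    return out
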