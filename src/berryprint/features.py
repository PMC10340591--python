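"""Feature extraction: the 775-dimensional fused descriptor.

Each image yields 768 Gabor texture-histogram values (256 per HSI channel)
followed by the 7 Hu invariant moments of the preprocessed grayscale
image, in that fixed order.  :class:`FruitFeatureExtractor` packages the
whole chain as a stateless scikit-learn transformer so it composes with
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import preprocess as pp
from .colorspace import rgb_to_hsi
from .shape import HU_FEATURE_LENGTH, hu_moments
from .texture import DEFAULT_GABOR_PARAMS, TEXTURE_FEATURE_LENGTH, GaborParams, gabor_features

__all__ = ["FEATURE_LENGTH", "FruitFeatureExtractor", "extract_features", "feature_names"]

FEATURE_LENGTH = TEXTURE_FEATURE_LENGTH + HU_FEATURE_LENGTH  # 775


def feature_names() -> list:
    """Column names f1..f768, h1..h7 used in feature tables."""
    return [f"f{i}" for i in range(1, TEXTURE_FEATURE_LENGTH + 1)] + [
        f"h{i}" for i in range(1, HU_FEATURE_LENGTH + 1)
    ]


class FruitFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform RGB fruit images into 775-dimensional feature vectors.

    Parameters
    ----------
    preprocess : run cropping/background unification first (disable when
        images are already preprocessed).
    grayscale_coeffs : (R, G, B) luma weights.
    gap_thresh : max gap (px) between edge coordinates merged into the
        object's bounding box; larger gaps are treated as noise.
    morph_radius : disk radius (px) of the closing/opening that cleans the
        object mask before the background is blackened.
    gabor_h, gabor_s, gabor_i : :class:`GaborParams` per HSI channel
        (``None`` → package defaults).
    hist_bins : histogram bins per channel (256 → 768 texture features).
    normalize_hist : divide histogram counts by pixel count, making images
        of different sizes comparable.
    fuse : how real/imaginary Gabor responses combine ("magnitude" or "sum").

    The transformer is stateless: ``fit`` only records the output width.
    """

    def __init__(
        self,
        preprocess: bool = True,
        grayscale_coeffs: tuple = pp.GRAY_COEFFS,
        gap_thresh: int = 10,
        morph_radius: int = 3,
        gabor_h: GaborParams | None = None,
        gabor_s: GaborParams | None = None,
        gabor_i: GaborParams | None = None,
        hist_bins: int = 256,
        normalize_hist: bool = False,
        fuse: str = "magnitude",
    ):
        self.preprocess = preprocess
        self.grayscale_coeffs = grayscale_coeffs
        self.gap_thresh = gap_thresh
        self.morph_radius = morph_radius
        self.gabor_h = gabor_h
        self.gabor_s = gabor_s
        self.gabor_i = gabor_i
        self.hist_bins = hist_bins
        self.normalize_hist = normalize_hist
        self.fuse = fuse

    def fit(self, X=None, y=None):
        self.n_features_out_ = 3 * self.hist_bins + HU_FEATURE_LENGTH
        return self

    def transform_one(self, img: np.ndarray) -> np.ndarray:
        """Feature vector of a single image."""
        img = np.asarray(img)
        if self.preprocess:
            img = pp.preprocess_image(
                img,
                coeffs=self.grayscale_coeffs,
                gap_thresh=self.gap_thresh,
                morph_radius=self.morph_radius,
            )
        hsi = rgb_to_hsi(img)
        tex = gabor_features(
            hsi,
            self.gabor_h or DEFAULT_GABOR_PARAMS["h"],
            self.gabor_s or DEFAULT_GABOR_PARAMS["s"],
            self.gabor_i or DEFAULT_GABOR_PARAMS["i"],
            bins=self.hist_bins,
            normalize=self.normalize_hist,
            fuse=self.fuse,
        )
        gray = pp.to_grayscale(img, self.grayscale_coeffs)
        hu = hu_moments(gray)
        return np.concatenate([tex, hu])

    def transform(self, X) -> np.ndarray:
        """Feature matrix for a sequence of images (list of H×W×3 arrays)."""
        if isinstance(X, np.ndarray) and X.ndim == 3:
            X = [X]
        rows = []
        for i, img in enumerate(X):
            try:
                rows.append(self.transform_one(img))
            except Exception as exc:
                raise type(exc)(f"sample {i}: {exc}") from exc
        return np.asarray(rows)


def extract_features(img: np.ndarray, extractor: FruitFeatureExtractor | None = None, **kwargs) -> np.ndarray:
    """Feature vector of one image (thin wrapper over the transformer)."""
    ex = extractor if extractor is not None else FruitFeatureExtractor(**kwargs)
    return ex.transform_one(np.asarray(img))
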