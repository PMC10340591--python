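"""Hu invariant moments — the 7-dimensional shape descriptor.

The seven Hu invariants are algebraic combinations of normalized central
moments of the grayscale image; they are invariant to translation, rotation
and (after normalization) spatial scale, and the seventh flips sign under
mirroring.  Index convention: x runs over rows 1..m and y over columns 1..n
(1-based), matching the classical double-sum definition; the invariance
properties make the choice immaterial but it is fixed so independent
oracles can reproduce the raw moments exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EmptyImageError",
    "raw_moment",
    "central_moment",
    "normalized_moment",
    "hu_moments",
    "HU_FEATURE_LENGTH",
]

HU_FEATURE_LENGTH = 7


class EmptyImageError(ValueError):
    """Raised when a moment is requested of an all-zero image."""


def _as_image(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("moments expect a 2-D grayscale image")
    if not a.any():
        raise EmptyImageError("empty image: all pixel values are zero")
    return a


def _grids(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m, n = a.shape
    x = np.arange(1, m + 1, dtype=float)[:, None]  # rows
    y = np.arange(1, n + 1, dtype=float)[None, :]  # columns
    return x, y


def raw_moment(img: np.ndarray, p: int, q: int) -> float:
    """Ordinary moment m_pq = Σ_x Σ_y x^p · y^q · I(x, y), 1-based indices."""
    if p < 0 or q < 0:
        raise ValueError("moment orders must be non-negative")
    a = _as_image(img)
    x, y = _grids(a)
    return float(((x**p) * (y**q) * a).sum())


def centroid(img: np.ndarray) -> tuple[float, float]:
    """Intensity centroid (x̄, ȳ) = (m10/m00, m01/m00)."""
    a = _as_image(img)
    x, y = _grids(a)
    m00 = a.sum()
    return float((x * a).sum() / m00), float((y * a).sum() / m00)


def central_moment(img: np.ndarray, p: int, q: int) -> float:
    """Central moment μ_pq = Σ (x − x̄)^p (y − ȳ)^q I(x, y)."""
    if p < 0 or q < 0:
        raise ValueError("moment orders must be non-negative")
    a = _as_image(img)
    x, y = _grids(a)
    xbar, ybar = centroid(a)
    return float((((x - xbar) ** p) * ((y - ybar) ** q) * a).sum())


def normalized_moment(img: np.ndarray, p: int, q: int) -> float:
    """Scale-normalized central moment e_pq = μ_pq / μ00^((p+q+2)/2), p+q ≥ 2."""
    if p + q < 2:
        raise ValueError("normalized moments require p + q >= 2")
    a = _as_image(img)
    mu00 = a.sum()
    return central_moment(a, p, q) / mu00 ** ((p + q + 2) / 2.0)


def hu_moments(img: np.ndarray) -> np.ndarray:
    """The seven Hu invariants H1..H7 of a grayscale image, in fixed order.

    Raw values are returned (no log transform); a display-side log mapping
    is left to plotting code.
    """
    a = _as_image(img)
    x, y = _grids(a)
    mu00 = a.sum()
    xbar = float((x * a).sum() / mu00)
    ybar = float((y * a).sum() / mu00)
    dx = x - xbar
    dy = y - ybar

    def e(p: int, q: int) -> float:
        mu = float(((dx**p) * (dy**q) * a).sum())
        return mu / mu00 ** ((p + q + 2) / 2.0)

    e20, e02, e11 = e(2, 0), e(0, 2), e(1, 1)
    e30, e03, e21, e12 = e(3, 0), e(0, 3), e(2, 1), e(1, 2)

    h1 = e20 + e02
    h2 = (e20 - e02) ** 2 + 4.0 * e11**2
    h3 = (e30 - 3.0 * e12) ** 2 + (3.0 * e21 - e03) ** 2
    h4 = (e30 + e12) ** 2 + (e21 + e03) ** 2
    h5 = (e30 - 3.0 * e12) * (e30 + e12) * ((e30 + e12) ** 2 - 3.0 * (e21 + e03) ** 2) + (
        3.0 * e21 - e03
    ) * (e21 + e03) * (3.0 * (e30 + e12) ** 2 - (e21 + e03) ** 2)
    h6 = (e20 - e02) * ((e30 + e12) ** 2 - (e21 + e03) ** 2) + 4.0 * e11 * (e30 + e12) * (
        e21 + e03
    )
    h7 = (3.0 * e21 - e03) * (e30 + e12) * ((e30 + e12) ** 2 - 3.0 * (e21 + e03) ** 2) - (
        e30 - 3.0 * e12
    ) * (e21 + e03) * (3.0 * (e30 + e12) ** 2 - (e21 + e03) ** 2)

    return np.array([h1, h2, h3, h4, h5, h6, h7], dtype=float)
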