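"""RGB → HSI (hue, saturation, intensity) color-space transformation.

HSI mirrors how humans describe color — an angular hue, a chromatic purity,
and a brightness equal to the channel mean — and is less sensitive to
illumination changes than raw RGB, which is why texture features are
extracted per HSI channel rather than per RGB channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HsiImage", "rgb_to_hsi"]

TWO_PI = 2.0 * np.pi


@dataclass
class HsiImage:
    """Per-pixel hue (radians in [0, 2π)), saturation ([0, 1]) and intensity
    ([0, 255] scale, the exact mean of R, G, B)."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.hue.shape

    def stack(self) -> np.ndarray:
        """H×W×3 array with channels (hue, saturation, intensity)."""
        return np.stack([self.hue, self.saturation, self.intensity], axis=-1)


def rgb_to_hsi(img: np.ndarray) -> HsiImage:
    """Convert an RGB raster to HSI.

    For each pixel with channels (R, G, B):

    * intensity  I = (R + G + B) / 3
    * saturation S = 1 − 3·min(R, G, B) / (R + G + B)
    * hue        H = θ if G ≥ B else 2π − θ, where
      θ = arccos( 0.5·[(R−G) + (R−B)] / sqrt((R−G)² + (R−B)(G−B)) )

    Degenerate pixels get defined fallbacks rather than NaN: black pixels
    (R+G+B = 0) map to H = S = I = 0, and gray pixels (R = G = B) have an
    undefined hue which is set to 0.  The arccos argument is clamped to
    [−1, 1] to absorb floating-point overshoot.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {a.shape}")
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    total = r + g + b

    intensity = total / 3.0

    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    chromatic = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arccos(np.clip(np.where(chromatic, num / np.where(chromatic, den, 1.0), 1.0), -1.0, 1.0))
    hue = np.where(g >= b, theta, TWO_PI - theta)
    hue = np.where(chromatic, hue, 0.0) % TWO_PI

    return HsiImage(hue=hue, saturation=saturation, intensity=intensity)
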