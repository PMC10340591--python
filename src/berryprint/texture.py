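"""Gabor-filter texture features on the HSI channels.

One complex Gabor filter is applied per HSI channel; the magnitude of the
complex response is histogrammed into 256 bins, and the three histograms
are concatenated into a 768-dimensional texture descriptor.  The default
filter bank uses wavelengths (13, 10, 10) px and orientations
(π/4, π/3, π/12) for the H, S and I channels respectively, phase 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .colorspace import TWO_PI, HsiImage

__all__ = [
    "GaborParams",
    "DEFAULT_GABOR_PARAMS",
    "gabor_kernel",
    "gabor_response",
    "channel_histogram",
    "gabor_features",
    "TEXTURE_FEATURE_LENGTH",
]

TEXTURE_FEATURE_LENGTH = 768


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one complex Gabor filter.

    wavelength λ and envelope width σ are in pixels; orientation θ and
    phase φ in radians; gamma γ is the envelope aspect ratio.  When not
    given, σ defaults to 0.56·λ (≈ one octave of spatial-frequency
    bandwidth) and the kernel half-width to ceil(3σ·max(1, 1/γ)), i.e. the
    Gaussian envelope truncated at three standard deviations along its
    longest axis.
    """

    wavelength: float
    orientation: float = 0.0
    phase: float = 0.0
    sigma: float | None = None
    gamma: float = 0.5
    halfwidth: int | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.halfwidth is not None and self.halfwidth < 1:
            raise ValueError("halfwidth must be >= 1")

    @property
    def sigma_(self) -> float:
        return self.sigma if self.sigma is not None else 0.56 * self.wavelength

    @property
    def halfwidth_(self) -> int:
        if self.halfwidth is not None:
            return self.halfwidth
        return math.ceil(3.0 * self.sigma_ * max(1.0, 1.0 / self.gamma))


#: Per-channel defaults: H, S, I.
DEFAULT_GABOR_PARAMS = {
    "h": GaborParams(wavelength=13, orientation=np.pi / 4, phase=0.0),
    "s": GaborParams(wavelength=10, orientation=np.pi / 3, phase=0.0),
    "i": GaborParams(wavelength=10, orientation=np.pi / 12, phase=0.0),
}


def gabor_kernel(p: GaborParams) -> np.ndarray:
    """Complex Gabor kernel evaluated on the integer grid centered at 0.

    kernel[y, x] = exp(−(x'² + γ²·y'²)/(2σ²)) · exp(i·(2π·x'/λ + φ)) with
    x' = x·cosθ + y·sinθ and y' = y·cosθ − x·sinθ; x indexes columns and
    y rows, both running over [−halfwidth, halfwidth].
    """
    hw = p.halfwidth_
    sigma = p.sigma_
    y, x = np.mgrid[-hw : hw + 1, -hw : hw + 1].astype(float)
    c, s = np.cos(p.orientation), np.sin(p.orientation)
    xp = x * c + y * s
    yp = y * c - x * s
    envelope = np.exp(-(xp**2 + p.gamma**2 * yp**2) / (2.0 * sigma**2))
    carrier = np.exp(1j * (TWO_PI * xp / p.wavelength + p.phase))
    return envelope * carrier


def gabor_response(channel: np.ndarray, p: GaborParams, fuse: str = "magnitude") -> np.ndarray:
    """Filter a channel with the complex Gabor kernel and fuse the parts.

    The channel is convolved with the real and imaginary parts of the
    kernel (replicate padding, same-size output); the two responses are
    fused either as the complex magnitude sqrt(re² + im²) (default, the
    standard Gabor energy) or as their plain sum (``fuse="sum"``).
    """
    a = np.asarray(channel, dtype=float)
    if a.ndim != 2:
        raise ValueError("gabor_response expects a 2-D channel")
    if not np.isfinite(a).all():
        raise ValueError("channel must be finite-valued")
    k = gabor_kernel(p)
    hw = p.halfwidth_
    padded = np.pad(a, hw, mode="edge")
    resp = fftconvolve(padded, k, mode="valid")
    if fuse == "magnitude":
        return np.abs(resp)
    if fuse == "sum":
        return resp.real + resp.imag
    raise ValueError("fuse must be 'magnitude' or 'sum'")


def channel_histogram(response: np.ndarray, bins: int = 256, normalize: bool = False) -> np.ndarray:
    """Histogram of a filter response after min–max rescaling to [0, bins−1].

    The response is linearly rescaled so its minimum maps to 0 and its
    maximum to ``bins − 1``, rounded to integers and counted.  A constant
    response puts all mass in bin 0.  With ``normalize`` the counts are
    divided by the pixel count so images of different sizes are comparable.
    """
    r = np.asarray(response, dtype=float).ravel()
    lo, hi = r.min(), r.max()
    # a spread below ~1e-9 relative is floating-point noise on an
    # algebraically constant response; rescaling it would amplify noise
    # to full histogram scale
    if hi - lo > 1e-9 * max(abs(hi), abs(lo), 1.0):
        q = np.rint((r - lo) / (hi - lo) * (bins - 1)).astype(np.int64)
    else:
        q = np.zeros(r.size, dtype=np.int64)
    hist = np.bincount(q, minlength=bins).astype(float)
    if normalize:
        hist /= r.size
    return hist


def gabor_features(
    hsi: HsiImage,
    params_h: GaborParams | None = None,
    params_s: GaborParams | None = None,
    params_i: GaborParams | None = None,
    *,
    bins: int = 256,
    normalize: bool = False,
    fuse: str = "magnitude",
) -> np.ndarray:
    """768-dimensional texture feature: per-channel Gabor response histograms.

    The hue channel is rescaled from [0, 2π) to [0, 255] before filtering so
    the three channels share comparable dynamics.  The output concatenates
    the H-channel histogram (bins 0–255), S (256–511) and I (512–767).
    """
    params_h = params_h or DEFAULT_GABOR_PARAMS["h"]
    params_s = params_s or DEFAULT_GABOR_PARAMS["s"]
    params_i = params_i or DEFAULT_GABOR_PARAMS["i"]
    hue_scaled = hsi.hue * (255.0 / TWO_PI)
    parts = [
        channel_histogram(gabor_response(hue_scaled, params_h, fuse), bins, normalize),
        channel_histogram(gabor_response(hsi.saturation, params_s, fuse), bins, normalize),
        channel_histogram(gabor_response(hsi.intensity, params_i, fuse), bins, normalize),
    ]
    return np.concatenate(parts)


def reciprocal_wavelengths(params: GaborParams) -> GaborParams:
    """Reinterpret the wavelength field as a spatial frequency (1/λ)."""
    return replace(params, wavelength=1.0 / params.wavelength, sigma=params.sigma)
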