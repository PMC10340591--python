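"""YAML-backed configuration exposing every tunable of the pipeline."""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .classify import RfConfig
from .features import FruitFeatureExtractor
from .texture import GaborParams

__all__ = ["DEFAULT_CONFIG", "load_config", "extractor_from_config", "rf_from_config"]

DEFAULT_CONFIG = {
    "grayscale": {"coeffs": [0.299, 0.587, 0.114]},
    "crop": {"gap_thresh": 10},
    "morphology": {"radius": 3},
    "gabor": {
        # per-channel wavelength (px), orientation (rad), phase (rad)
        "h": {"wavelength": 13, "orientation": math.pi / 4, "phase": 0.0},
        "s": {"wavelength": 10, "orientation": math.pi / 3, "phase": 0.0},
        "i": {"wavelength": 10, "orientation": math.pi / 12, "phase": 0.0},
        "gamma": 0.5,
        "sigma_factor": 0.56,  # sigma = sigma_factor * wavelength
        "lambda_is_reciprocal": False,
        "fuse": "magnitude",
    },
    "histogram": {"bins": 256, "normalize": False},
    "preprocess": {"enabled": True},
    "rf": {"n_trees": 2000, "mtry": 50, "seed": None},
    "eval": {"train_fraction": 0.8, "repeats": 200, "seed": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file (deep-merged)."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def _gabor_params(cfg: dict, channel: str) -> GaborParams:
    g = cfg["gabor"]
    chan = g[channel]
    wavelength = float(chan["wavelength"])
    if g.get("lambda_is_reciprocal"):
        wavelength = 1.0 / wavelength
    return GaborParams(
        wavelength=wavelength,
        orientation=float(chan.get("orientation", 0.0)),
        phase=float(chan.get("phase", 0.0)),
        sigma=float(g["sigma_factor"]) * wavelength,
        gamma=float(g["gamma"]),
    )


def extractor_from_config(cfg: dict) -> FruitFeatureExtractor:
    return FruitFeatureExtractor(
        preprocess=bool(cfg["preprocess"]["enabled"]),
        grayscale_coeffs=tuple(cfg["grayscale"]["coeffs"]),
        gap_thresh=int(cfg["crop"]["gap_thresh"]),
        morph_radius=int(cfg["morphology"]["radius"]),
        gabor_h=_gabor_params(cfg, "h"),
        gabor_s=_gabor_params(cfg, "s"),
        gabor_i=_gabor_params(cfg, "i"),
        hist_bins=int(cfg["histogram"]["bins"]),
        normalize_hist=bool(cfg["histogram"]["normalize"]),
        fuse=str(cfg["gabor"]["fuse"]),
    )


def rf_from_config(cfg: dict) -> RfConfig:
    r = cfg["rf"]
    return RfConfig(n_trees=int(r["n_trees"]), mtry=int(r["mtry"]), seed=r.get("seed"))
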