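"""Training-time augmentation: a RandAugment-style policy for ultrasound.

Per image, N is drawn uniformly from a configured range, N distinct
transforms are sampled from an ultrasound-appropriate set, and each is
applied with a magnitude drawn from its range.  All transforms preserve the
canonical 384x576 [0, 1] contract and the GA label.  Geometric transforms
fill exposed borders with 0 (ultrasound background is black).

Default magnitudes are deliberately mild: re-scaling in particular perturbs
apparent structure size, the very cue that predicts GA, so its range is kept
narrow (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import rescale, rotate

from .phantom import CANONICAL_SHAPE

DEFAULT_MAGNITUDES: Dict[str, Tuple[float, float]] = {
    "rotation": (-20.0, 20.0),          # degrees
    "rescale": (0.9, 1.1),              # zoom factor
    "hflip": (1.0, 1.0),                # parameter-free
    "blur": (0.0, 1.5),                 # Gaussian sigma, px
    "brightness_contrast": (-0.15, 0.15),
    "mult_noise": (0.05, 0.05),         # pixel-wise log-normal sigma
    "grid_distortion": (0.0, 0.05),     # max displacement, fraction of height
}


def _fit_canonical(img: np.ndarray) -> np.ndarray:
    """Center-crop or zero-pad back to the canonical shape."""
    h, w = CANONICAL_SHAPE
    out = np.zeros((h, w), dtype=img.dtype)
    ih, iw = img.shape
    sy, sx = max(0, (ih - h) // 2), max(0, (iw - w) // 2)
    dy, dx = max(0, (h - ih) // 2), max(0, (w - iw) // 2)
    ch, cw = min(h, ih), min(w, iw)
    out[dy : dy + ch, dx : dx + cw] = img[sy : sy + ch, sx : sx + cw]
    return out


def _t_rotation(img, mag, rng):
    return rotate(img, mag, order=1, mode="constant", cval=0.0, preserve_range=True)


def _t_rescale(img, mag, rng):
    scaled = rescale(img, mag, order=1, mode="constant", cval=0.0, preserve_range=True)
    return _fit_canonical(scaled)


def _t_hflip(img, mag, rng):
    return img[:, ::-1]


def _t_blur(img, mag, rng):
    return ndimage.gaussian_filter(img, mag) if mag > 0 else img


def _t_brightness_contrast(img, mag, rng):
    # One draw drives brightness; an independent sign drives contrast of the
    # same magnitude, matching the "brightness & contrast jitter" pairing.
    contrast = 1.0 + mag * (1.0 if rng.random() < 0.5 else -1.0)
    return (img - 0.5) * contrast + 0.5 + mag


def _t_mult_noise(img, mag, rng):
    if mag <= 0:
        return img
    return img * np.exp(rng.normal(-0.5 * mag**2, mag, img.shape))


def _t_grid_distortion(img, mag, rng):
    if mag <= 0:
        return img
    h, w = img.shape
    amp = mag * h
    grid = (5, 7)
    dy = ndimage.zoom(rng.uniform(-amp, amp, grid), (h / grid[0], w / grid[1]), order=1)
    dx = ndimage.zoom(rng.uniform(-amp, amp, grid), (h / grid[0], w / grid[1]), order=1)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.array([yy + dy[:h, :w], xx + dx[:h, :w]])
    return ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)


_TRANSFORMS = {
    "rotation": _t_rotation,
    "rescale": _t_rescale,
    "hflip": _t_hflip,
    "blur": _t_blur,
    "brightness_contrast": _t_brightness_contrast,
    "mult_noise": _t_mult_noise,
    "grid_distortion": _t_grid_distortion,
}


@dataclass(frozen=True)
class AugmentPolicy:
    """A RandAugment-style policy: transform set, randomized N, magnitudes."""

    transform_set: Tuple[str, ...] = tuple(_TRANSFORMS)
    n_range: Tuple[int, int] = (1, 3)
    magnitude_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MAGNITUDES)
    )

    def __post_init__(self) -> None:
        unknown = set(self.transform_set) - set(_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")
        lo, hi = self.n_range
        if not (0 <= lo <= hi <= len(self.transform_set)):
            raise ValueError("n_range must lie within [0, |transform_set|]")
        for name, (mlo, mhi) in self.magnitude_ranges.items():
            if not (np.isfinite(mlo) and np.isfinite(mhi)):
                raise ValueError(f"magnitude range for {name} must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "transform_set": list(self.transform_set),
                "n_range": list(self.n_range),
                "magnitude_ranges": {k: list(v) for k, v in self.magnitude_ranges.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AugmentPolicy":
        d = json.loads(text)
        return cls(
            transform_set=tuple(d["transform_set"]),
            n_range=tuple(d["n_range"]),
            magnitude_ranges={k: tuple(v) for k, v in d["magnitude_ranges"].items()},
        )


def apply_augment(image: np.ndarray, policy: AugmentPolicy, seed: int) -> np.ndarray:
    """Apply the policy to one canonical frame, deterministically per seed."""
    if image.shape != CANONICAL_SHAPE:
        raise ValueError(f"augmentation expects canonical {CANONICAL_SHAPE} frames")
    rng = np.random.default_rng(seed)
    lo, hi = policy.n_range
    n = int(rng.integers(lo, hi + 1))
    out = np.asarray(image, dtype=np.float64)
    if n == 0:
        return out.astype(np.float32)
    names = list(policy.transform_set)
    chosen = rng.choice(len(names), size=n, replace=False)
    for idx in chosen:
        name = names[int(idx)]
        mlo, mhi = policy.magnitude_ranges.get(name, DEFAULT_MAGNITUDES[name])
        mag = float(rng.uniform(mlo, mhi))
        out = _TRANSFORMS[name](out, mag, rng)
    out = np.clip(out, 0.0, 1.0)
    if out.shape != CANONICAL_SHAPE:
        out = _fit_canonical(out)
    return out.astype(np.float32)
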