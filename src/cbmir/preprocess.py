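"""Slice-to-tensor preprocessing and training-time augmentation.

Raw 16-bit slices are converted to model inputs by per-image min–max scaling
to [0, 1], bilinear resize to 224×224, and replication of the grayscale
plane into 3 identical channels so the input matches a conventional RGB
backbone.  Per-image min–max is used because raw 16-bit DICOM intensity
ranges vary from image to image and no windowing metadata is modeled; it
also makes the transform invariant to affine intensity maps ``a·x + b``
with ``a > 0``.

Optional per-channel standardization (the ImageNet constants, documented
below) can be applied after stacking; it is off by default so the three
channels stay identical.

Augmentation — mild random rotation, horizontal flip and isotropic scaling —
is applied to training images only; test-tagged inputs always pass through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "MODEL_INPUT_SIZE",
    "CHANNEL_MEAN",
    "CHANNEL_STD",
    "AugmentParams",
    "to_model_input",
    "augment",
]

MODEL_INPUT_SIZE = 224

#: Per-channel standardization constants (the ImageNet statistics), applied
#: only when ``standardize=True``.
CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class AugmentParams:
    """Training-time augmentation magnitudes (kinds per the method; mild defaults)."""

    rotation_deg: float = 15.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    enabled: bool = True

    def __post_init__(self):
        for p in (self.hflip_prob, self.vflip_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("flip probabilities must be in [0, 1]")
        if not (0.0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale_range must be a positive (lo, hi) pair")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(rotation_deg=0.0, hflip_prob=0.0, vflip_prob=0.0, scale_range=(1.0, 1.0), enabled=False)


def to_model_input(pixels: np.ndarray, standardize: bool = False) -> np.ndarray:
    """Convert a 2-D intensity image to a (3, 224, 224) float32 model input.

    Steps: per-image min–max scaling to [0, 1] (a constant image maps to all
    zeros rather than dividing by zero), bilinear resize, stacking into 3
    identical channels, then optional per-channel standardization.
    """
    px = np.asarray(pixels)
    if px.ndim != 2 or px.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {px.shape}")
    px = px.astype(np.float32)
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        px = (px - lo) / (hi - lo)
    else:
        px = np.zeros_like(px)
    if px.shape != (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE):
        im = Image.fromarray(px, mode="F")
        im = im.resize((MODEL_INPUT_SIZE, MODEL_INPUT_SIZE), resample=Image.BILINEAR)
        px = np.asarray(im, dtype=np.float32).copy()
        np.clip(px, 0.0, 1.0, out=px)
    out = np.repeat(px[None, :, :], 3, axis=0)
    if standardize:
        out = (out - CHANNEL_MEAN[:, None, None]) / CHANNEL_STD[:, None, None]
    return np.ascontiguousarray(out, dtype=np.float32)


def _affine_channel(ch: np.ndarray, angle_deg: float, scale: float) -> np.ndarray:
    """Rotate and scale one channel about its center in a single resampling."""
    h, w = ch.shape
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mat = rot / scale  # output->input mapping
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center
    return ndimage.affine_transform(ch, mat, offset=offset, order=1, mode="constant", cval=0.0)


def augment(
    x: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator,
    split: str = "train",
) -> np.ndarray:
    """Apply sampled rotation / flip / scale to a (3, H, W) model input.

    Identity when augmentation is disabled or when ``split`` is ``"test"``:
    held-out images are never augmented so evaluation reflects the images as
    acquired.
    """
    if split == "test" or not params.enabled:
        return x
    out = x
    if params.hflip_prob > 0 and rng.uniform() < params.hflip_prob:
        out = out[:, :, ::-1]
    if params.vflip_prob > 0 and rng.uniform() < params.vflip_prob:
        out = out[:, ::-1, :]
    angle = float(rng.uniform(-params.rotation_deg, params.rotation_deg)) if params.rotation_deg else 0.0
    lo, hi = params.scale_range
    scale = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    if angle != 0.0 or scale != 1.0:
        out = np.ascontiguousarray(out)
        if np.array_equal(out[0], out[1]) and np.array_equal(out[1], out[2]):
            # channels identical by construction: transform once, re-stack
            ch = _affine_channel(out[0], angle, scale)
            out = np.repeat(ch[None], 3, axis=0)
        else:
            out = np.stack([_affine_channel(c, angle, scale) for c in out])
    return np.ascontiguousarray(out, dtype=np.float32)
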