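"""Chest-X-ray-style preprocessing and augmentation.

The preprocessing chain for raw radiographs: min–max normalisation to
[0, 255], polarity correction (inversion when air renders dark), and
global histogram equalisation; training-time augmentation is a small
random rotation (|angle| ≤ 10°, random sign) plus independent horizontal
and vertical mirror flips.  Everything here also serves the 32×32
toy-image path used in tests.

Whether a radiograph needs inversion is decided by a border-versus-centre
heuristic: in an air-white image the border (air) is brighter than the
centre (tissue), so an image whose outer 10% frame is *darker* on average
than its centre is inverted.
"""

from __future__ import annotations

import numpy as np
from skimage import transform

__all__ = [
    "preprocess_cxr",
    "augment",
    "resize_to_input",
    "needs_inversion",
    "to_jpg",
]

BORDER_FRAC = 0.1


def _as_float(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite pixel values")
    return arr


def needs_inversion(img: np.ndarray) -> bool:
    """True when the border (air region) is darker than the centre."""
    arr = _as_float(img)
    h, w = arr.shape[:2]
    bh, bw = max(1, int(round(BORDER_FRAC * h))), max(1, int(round(BORDER_FRAC * w)))
    border_mask = np.zeros((h, w), dtype=bool)
    border_mask[:bh, :] = border_mask[-bh:, :] = True
    border_mask[:, :bw] = border_mask[:, -bw:] = True
    return float(arr[border_mask].mean()) < float(arr[~border_mask].mean())


def preprocess_cxr(img) -> np.ndarray:
    """Normalise → invert if necessary → histogram-equalise; 8-bit output.

    Constant images are passed through unchanged (equalisation of a
    degenerate histogram is a no-op here).  Output is uint8 in [0, 255].
    """
    arr = _as_float(img)
    if arr.ndim != 2:
        raise ValueError("preprocess_cxr expects a single-channel image")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.clip(np.round(arr), 0, 255).astype(np.uint8)
    arr = (arr - lo) / (hi - lo) * 255.0
    if needs_inversion(arr):
        arr = 255.0 - arr
    levels = np.round(arr).astype(np.uint8)
    # global equalisation via the integer cumulative histogram: maps the
    # empirical cdf onto a uniform target over the 256 levels; applying it
    # to its own output moves pixels by at most one level
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist) / levels.size
    lut = np.round(255.0 * cdf).astype(np.uint8)
    return lut[levels]


def augment(img, seed: int) -> np.ndarray:
    """Random rotation (|angle| ~ U[0°,10°], random sign) and mirror flips.

    Horizontal and vertical flips are independent fair coins.  Shape is
    preserved; rotation fills the exposed corners with black (0).
    Deterministic under ``seed``.
    """
    arr = _as_float(img)
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(0.0, 10.0)) * (1.0 if rng.random() < 0.5 else -1.0)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    out = transform.rotate(
        arr, angle, resize=False, mode="constant", cval=0.0, order=1,
        preserve_range=True,
    )
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def resize_to_input(img, side: int = 224) -> np.ndarray:
    """Bilinear resize to ``side×side×3``; grayscale is replicated to 3 channels."""
    arr = _as_float(img)
    if arr.ndim not in (2, 3):
        raise ValueError("expected h×w or h×w×c image")
    if 0 in arr.shape:
        raise ValueError("zero-dimension image")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    out = transform.resize(
        arr, (side, side, arr.shape[2]), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    if out.shape[2] == 1:
        out = np.repeat(out, 3, axis=2)
    return out


def to_jpg(img: np.ndarray, path, quality: int = 95) -> None:
    """Save an 8-bit image as JPG (dataset-conversion utility only —
    lossy round-trips are kept out of the training loader)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8), quality=quality)
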