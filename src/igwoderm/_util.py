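"""Shared 8-bit image helpers."""
from __future__ import annotations

import numpy as np

#: ITU-R BT.601 luminance weights used for every grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def round_half_up(x) -> np.ndarray:
    """Deterministic round-half-up (floor(x + 0.5))."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def as_image(img) -> np.ndarray:
    """Validate and return an 8-bit image array (H x W or H x W x 3)."""
    arr = np.asarray(img)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise ValueError("expected a non-empty H x W or H x W x 3 image")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError("color images must have exactly 3 channels")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating):
            arr = round_half_up(arr)
        arr = np.asarray(arr)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("image intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def to_uint8(arr) -> np.ndarray:
    """Round (half-up), clip to [0, 255] and cast."""
    return np.clip(round_half_up(arr), 0, 255).astype(np.uint8)


def to_gray(img) -> np.ndarray:
    """Luminance grayscale (0.299 R + 0.587 G + 0.114 B, rounded half-up)."""
    arr = as_image(img)
    if arr.ndim == 2:
        return arr
    w = np.asarray(LUMA_WEIGHTS)
    return to_uint8(arr.astype(float) @ w)
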