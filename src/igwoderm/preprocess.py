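"""Dermoscopic image conditioning: denoising, hair removal, contrast stretch.

Dermoscopy frames routinely carry sensor noise, occluding hairs and poor
contrast.  The conditioning chain applied before segmentation/classification
is

1. :func:`gaussian_denoise` — Gaussian low-pass filtering per channel;
2. :func:`remove_hair` — a DullRazor-style detector: grayscale morphological
   closing lifts thin dark structures to the local background, the closing
   difference is thresholded into a boolean artifact mask, small mask
   components are discarded as noise, and masked pixels are inpainted;
3. :func:`enhance_contrast` — per-channel min-max stretch to [0, 255] applied
   through a 256-entry lookup table.

All operations accept and return 8-bit images.  :class:`DermoscopyPreprocessor`
wraps the chain as a scikit-learn transformer over image batches.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

from ._util import as_image, round_half_up, to_gray, to_uint8

__all__ = [
    "ContrastLUT",
    "HairMask",
    "gaussian_denoise",
    "remove_hair",
    "build_contrast_lut",
    "enhance_contrast",
    "DermoscopyPreprocessor",
]

_CLEAN_ELEMENT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ContrastLUT:
    """256-entry intensity map of a min-max stretch."""

    table: np.ndarray
    in_min: int
    in_max: int

    def apply(self, channel: np.ndarray) -> np.ndarray:
        return self.table[channel]


@dataclass(frozen=True)
class HairMask:
    """Boolean artifact mask plus the fraction of flagged pixels."""

    mask: np.ndarray
    coverage_fraction: float


def gaussian_denoise(img, sigma: float) -> np.ndarray:
    """Gaussian low-pass filter with standard deviation ``sigma`` (pixels).

    ``sigma == 0`` is the identity.  The normalized kernel preserves constant
    regions exactly; output is re-quantized to 8 bits.
    """
    arr = as_image(img)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return arr.copy()
    out = np.empty_like(arr)
    if arr.ndim == 2:
        out[:] = to_uint8(ndi.gaussian_filter(arr.astype(float), sigma))
    else:
        for c in range(3):
            out[..., c] = to_uint8(ndi.gaussian_filter(arr[..., c].astype(float), sigma))
    return out


def remove_hair(img, element_size: int = 7, threshold: int = 10,
                mode: str = "closing", median_radius: int = 5,
                min_component_area: int = 16) -> tuple[np.ndarray, HairMask]:
    """DullRazor-style removal of thin dark structures (hairs, ruler marks).

    Grayscale closing (dilate then erode) with a square ``element_size`` x
    ``element_size`` element fills dark structures thinner than the element;
    pixels whose closing raised the luminance by more than ``threshold``
    levels form the raw artifact mask.  The mask is denoised by dropping
    8-connected components smaller than ``min_component_area`` pixels (hairs
    are long, so their components are large; isolated texture specks are not)
    and consolidated with a 3x3 binary closing, which bridges one-pixel
    breaks along a stroke without thickening it away from the stroke.
    Masked pixels are replaced by the closed image ("closing" mode) or by the
    median of unmasked neighbours within ``median_radius`` ("median" mode).
    Pixels outside the returned mask are never modified.  Input should be
    denoised first — pixel noise inside a textured lesion otherwise exceeds
    the difference threshold.
    """
    if element_size < 3 or element_size % 2 == 0:
        raise ValueError("element_size must be an odd integer >= 3")
    if mode not in ("closing", "median"):
        raise ValueError("mode must be 'closing' or 'median'")
    arr = as_image(img)
    size = (element_size, element_size)
    if arr.ndim == 2:
        closed = ndi.grey_closing(arr, size=size)
        closed_gray = closed
        gray = arr
    else:
        closed = np.stack(
            [ndi.grey_closing(arr[..., c], size=size) for c in range(3)], axis=-1)
        closed_gray = to_gray(closed)
        gray = to_gray(arr)
    diff = np.abs(closed_gray.astype(int) - gray.astype(int))
    raw = diff > threshold
    labels, n = ndi.label(raw, structure=_CLEAN_ELEMENT)
    if n:
        sizes = ndi.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
        keep = np.concatenate([[False], sizes >= min_component_area])
        raw = keep[labels]
    mask = ndi.binary_erosion(
        ndi.binary_dilation(raw, structure=_CLEAN_ELEMENT),
        structure=_CLEAN_ELEMENT, border_value=1)
    out = arr.copy()
    if mode == "closing":
        out[mask] = closed[mask]
    else:
        out = _median_inpaint(arr, closed, mask, median_radius)
    cov = float(mask.sum()) / mask.size
    return out, HairMask(mask=mask, coverage_fraction=cov)


def _median_inpaint(arr: np.ndarray, closed: np.ndarray, mask: np.ndarray,
                    radius: int) -> np.ndarray:
    out = arr.copy()
    h, w = mask.shape
    for y, x in zip(*np.nonzero(mask)):
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        x0, x1 = max(0, x - radius), min(w, x + radius + 1)
        good = ~mask[y0:y1, x0:x1]
        if not good.any():
            out[y, x] = closed[y, x]  # fully masked neighbourhood
            continue
        window = arr[y0:y1, x0:x1]
        if arr.ndim == 2:
            out[y, x] = np.median(window[good])
        else:
            out[y, x] = [np.median(window[..., c][good]) for c in range(3)]
    return out


def build_contrast_lut(channel: np.ndarray) -> ContrastLUT:
    """LUT for a linear min-max stretch of one 8-bit channel.

    ``out[v] = round(255 * (v - in_min) / (in_max - in_min))`` with half-up
    rounding; a constant channel (``in_min == in_max``) maps to the identity.
    """
    lo, hi = int(channel.min()), int(channel.max())
    levels = np.arange(256, dtype=float)
    if lo == hi:
        table = np.arange(256, dtype=np.uint8)
    else:
        table = np.clip(round_half_up(255.0 * (levels - lo) / (hi - lo)),
                        0, 255).astype(np.uint8)
    return ContrastLUT(table=table, in_min=lo, in_max=hi)


def enhance_contrast(img) -> np.ndarray:
    """Per-channel min-max contrast stretch to the full 8-bit range."""
    arr = as_image(img)
    if arr.ndim == 2:
        return build_contrast_lut(arr).apply(arr)
    out = np.empty_like(arr)
    for c in range(3):
        out[..., c] = build_contrast_lut(arr[..., c]).apply(arr[..., c])
    return out


class DermoscopyPreprocessor(TransformerMixin, BaseEstimator):
    """Denoise -> hair removal -> contrast stretch over batches of images.

    A stateless transformer (``fit`` only validates parameters) so the chain
    can sit in front of a classifier inside an sklearn pipeline.  ``X`` is an
    ``(n, H, W)`` or ``(n, H, W, 3)`` stack of 8-bit images.
    """

    def __init__(self, denoise_sigma: float = 0.5, hair_element: int = 7,
                 hair_threshold: int = 10, hair_mode: str = "closing",
                 contrast: bool = True):
        self.denoise_sigma = denoise_sigma
        self.hair_element = hair_element
        self.hair_threshold = hair_threshold
        self.hair_mode = hair_mode
        self.contrast = contrast

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X[0]).size if len(X) else 0
        return self

    def transform(self, X):
        return np.stack([self.transform_one(img) for img in X])

    def transform_one(self, img) -> np.ndarray:
        out = gaussian_denoise(img, self.denoise_sigma)
        out, _ = remove_hair(out, element_size=self.hair_element,
                             threshold=self.hair_threshold, mode=self.hair_mode)
        if self.contrast:
            out = enhance_contrast(out)
        return out
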