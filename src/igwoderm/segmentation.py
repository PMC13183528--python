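"""Kapur-entropy multilevel thresholding and morphological lesion extraction.

Kapur's criterion picks thresholds ``TH = [th_1, ..., th_{m-1}]`` that
maximise the sum of the within-class Shannon entropies of the intensity
histogram,

    J(TH) = sum_j H_j,   H_j = -sum_{i in class j} (p_i / w_j) ln(p_i / w_j)

where ``w_j`` is the probability mass of class ``j`` (empty bins and empty
classes contribute zero).  The search over integer thresholds in [1, 254] is
driven by the grey wolf optimizer (:mod:`igwoderm.optimizer`), minimising
``-J``; following the study protocol the run is repeated (default 25 times)
with distinct sub-seeds and the final thresholds are the per-position mean of
the sorted per-run thresholds, rounded to integers.

Lesion extraction then binarises at the found threshold (the darker class is
the lesion by default), fills enclosed holes, opens, closes (3x3 structuring
element throughout) and keeps the largest 8-connected component.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

from ._util import as_image, round_half_up, to_gray
from .optimizer import IgwoConfig, SearchSpace, optimize

__all__ = [
    "Histogram",
    "ThresholdVector",
    "SegmentationConfig",
    "gray_histogram",
    "kapur_objective",
    "find_thresholds",
    "exhaustive_thresholds",
    "apply_thresholds",
    "lesion_mask_from_labels",
    "fill_holes",
    "open_mask",
    "close_mask",
    "largest_component",
    "segment_lesion",
    "KapurThresholder",
]

logger = logging.getLogger(__name__)

DEFAULT_ELEMENT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram with normalized probabilities."""

    counts: np.ndarray
    ph: np.ndarray
    L: int = 256

    @classmethod
    def from_counts(cls, counts) -> "Histogram":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (256,) or (counts < 0).any():
            raise ValueError("expected 256 non-negative bin counts")
        total = counts.sum()
        if total == 0:
            raise ValueError("histogram has no mass")
        return cls(counts=counts, ph=counts / total)

    def cumulatives(self) -> tuple[np.ndarray, np.ndarray]:
        """Prefix sums of ``p`` and ``p*ln(p)`` (leading zero, length 257)."""
        p = self.ph
        plogp = np.zeros_like(p)
        nz = p > 0
        plogp[nz] = p[nz] * np.log(p[nz])
        c1 = np.concatenate([[0.0], np.cumsum(p)])
        c2 = np.concatenate([[0.0], np.cumsum(plogp)])
        return c1, c2


@dataclass(frozen=True)
class ThresholdVector:
    """Strictly increasing integer thresholds in (0, 255) for ``m`` classes."""

    th: tuple[int, ...]
    m: int

    def __post_init__(self) -> None:
        th = tuple(int(v) for v in self.th)
        if len(th) != self.m - 1 or self.m < 2:
            raise ValueError("need m-1 thresholds for m >= 2 classes")
        if any(not 0 < v < 255 for v in th):
            raise ValueError("thresholds must lie strictly inside (0, 255)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "th", th)


def gray_histogram(img, channel: int | None = None) -> Histogram:
    """Histogram of the luminance image, or of one RGB channel (0, 1 or 2)."""
    arr = as_image(img)
    if channel is not None:
        if arr.ndim != 3:
            raise ValueError("channel selection requires an RGB image")
        arr = arr[..., channel]
    else:
        arr = to_gray(arr)
    counts = np.bincount(arr.ravel(), minlength=256)
    return Histogram.from_counts(counts)


def _kapur_batch(c1: np.ndarray, c2: np.ndarray, th: np.ndarray) -> np.ndarray:
    """J for a batch of integer threshold rows using histogram prefix sums.

    Per class, H = ln(w) - S/w with w the class mass and S = sum p ln p over
    the class; classes with zero mass contribute zero.
    """
    th = np.sort(np.asarray(th, dtype=int), axis=1)
    n = th.shape[0]
    bounds = np.concatenate(
        [np.zeros((n, 1), int), th, np.full((n, 1), 256)], axis=1)
    w = c1[bounds[:, 1:]] - c1[bounds[:, :-1]]
    s = c2[bounds[:, 1:]] - c2[bounds[:, :-1]]
    safe_w = np.where(w > 0, w, 1.0)
    h = np.where(w > 0, np.log(safe_w) - s / safe_w, 0.0)
    return h.sum(axis=1)


def kapur_objective(hist: Histogram, th) -> float:
    """Total within-class entropy J for one threshold vector.

    Thresholds are sorted internally, so the value is invariant under
    permutation of the inputs.  J >= 0 always; it is zero iff every occupied
    class has all its mass in a single bin.
    """
    if isinstance(th, ThresholdVector):
        th = th.th
    arr = np.atleast_1d(np.asarray(th, dtype=int))
    c1, c2 = hist.cumulatives()
    return float(_kapur_batch(c1, c2, arr[None, :])[0])


def exhaustive_thresholds(hist: Histogram, m: int = 2) -> tuple[tuple[int, ...], float]:
    """Brute-force maximiser of J over all integer threshold combinations.

    Supports m = 2 (254 candidates) and m = 3 (~32k candidate pairs); used as
    the independent oracle for the optimizer-driven search.
    """
    c1, c2 = hist.cumulatives()
    if m == 2:
        cands = np.arange(1, 255)[:, None]
    elif m == 3:
        a, b = np.meshgrid(np.arange(1, 255), np.arange(1, 255), indexing="ij")
        keep = a < b
        cands = np.stack([a[keep], b[keep]], axis=1)
    else:
        raise ValueError("exhaustive search implemented for m in {2, 3}")
    vals = _kapur_batch(c1, c2, cands)
    best = int(np.argmax(vals))
    return tuple(int(v) for v in cands[best]), float(vals[best])


def find_thresholds(source, m: int = 2, opt: IgwoConfig | None = None,
                    repeats: int = 25, variant: str = "igwo",
                    seed: int | None = None, return_details: bool = False):
    """Optimizer-driven Kapur thresholding.

    Parameters
    ----------
    source:
        An 8-bit image (converted to luminance) or a :class:`Histogram`.
    m:
        Number of classes (m - 1 thresholds).
    opt:
        Optimizer settings; defaults to the study protocol (N=30, T=200).
    repeats:
        Number of independently seeded optimizer runs (default 25).  The
        final thresholds are the per-position mean of the sorted per-run
        thresholds, rounded half-up; duplicates after rounding are resolved
        by incrementing (logged).
    """
    if m < 2:
        raise ValueError("need at least 2 classes")
    if m - 1 > 254:
        raise ValueError("more thresholds than interior intensity levels")
    if repeats < 1:
        raise ValueError("repeats must be positive")
    hist = source if isinstance(source, Histogram) else gray_histogram(source)
    c1, c2 = hist.cumulatives()

    def neg_entropy(X):
        return -_kapur_batch(c1, c2, X)

    space = SearchSpace(lower=np.ones(m - 1), upper=np.full(m - 1, 254.0),
                        integer_mask=np.ones(m - 1, dtype=bool))
    base = opt if opt is not None else IgwoConfig()
    master = seed if seed is not None else base.seed
    sub_seeds = np.random.SeedSequence(master).generate_state(repeats)
    per_run_th = np.empty((repeats, m - 1), dtype=float)
    per_run_j = np.empty(repeats)
    for r in range(repeats):
        cfg = replace(base, seed=int(sub_seeds[r]) & 0x7FFFFFFF)
        res = optimize(neg_entropy, space, cfg, variant=variant, vectorized=True)
        per_run_th[r] = np.sort(res.best_position)
        per_run_j[r] = -res.best_fitness
    th = round_half_up(per_run_th.mean(axis=0)).astype(int)
    th = np.sort(th)
    for i in range(1, th.size):
        if th[i] <= th[i - 1]:
            th[i] = th[i - 1] + 1
            logger.warning("duplicate threshold after averaging resolved by "
                           "incrementing to %d", th[i])
    th = np.clip(th, 1, 254)
    result = ThresholdVector(th=tuple(int(v) for v in th), m=m)
    if return_details:
        return result, {"per_run_thresholds": per_run_th,
                        "per_run_entropy": per_run_j,
                        "entropy": kapur_objective(hist, result)}
    return result


def apply_thresholds(img, th) -> np.ndarray:
    """Class-label image: pixel v gets class j with th_{j-1} <= v < th_j.

    Boundary convention: ``v >= th`` joins the upper class (th_0 = 0,
    th_m = 256).
    """
    if isinstance(th, ThresholdVector):
        th = th.th
    gray = to_gray(as_image(img))
    bins = np.sort(np.asarray(th, dtype=int))
    return np.digitize(gray, bins).astype(np.uint8)


def lesion_mask_from_labels(labels: np.ndarray, m: int,
                            foreground: str = "dark") -> np.ndarray:
    """Binary lesion mask from a class-label image.

    Melanocytic lesions are darker than surrounding skin in dermoscopy, so
    the darkest class is the default foreground.
    """
    if foreground == "dark":
        return labels == 0
    if foreground == "bright":
        return labels == m - 1
    raise ValueError("foreground must be 'dark' or 'bright'")


def _erode(mask: np.ndarray, e: np.ndarray) -> np.ndarray:
    return ndi.binary_erosion(mask, structure=e, border_value=1)


def _dilate(mask: np.ndarray, e: np.ndarray) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=e, border_value=0)


def _check_element(e) -> np.ndarray:
    e = DEFAULT_ELEMENT if e is None else np.asarray(e, dtype=bool)
    if e.ndim != 2 or any(s % 2 == 0 for s in e.shape) or not e.any():
        raise ValueError("structuring element must be odd-sized with a true cell")
    return e


def fill_holes(mask, e=None) -> np.ndarray:
    """Fill background regions not connected to the image border.

    Iterated conditional dilation of a border-seeded marker inside the
    background (X_k = dilate(X_{k-1}) intersect complement(A)) until a fixed
    point; unreached background pixels are the holes.  Extensive and
    idempotent; background touching the border is never filled.
    """
    e = _check_element(e)
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_fill_holes(mask, structure=e)


def open_mask(mask, e=None) -> np.ndarray:
    """Morphological opening (erode then dilate): removes small details."""
    e = _check_element(e)
    mask = np.asarray(mask, dtype=bool)
    return _dilate(_erode(mask, e), e)


def close_mask(mask, e=None) -> np.ndarray:
    """Morphological closing (dilate then erode): bridges narrow gaps."""
    e = _check_element(e)
    mask = np.asarray(mask, dtype=bool)
    return _erode(_dilate(mask, e), e)


_CONN8 = np.ones((3, 3), dtype=bool)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    labels, n = ndi.label(mask, structure=_CONN8)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for :func:`segment_lesion`.

    Defaults are desk scale (small optimizer budget, few repeats) so a single
    image segments in well under a second; the study-scale protocol is N=30,
    T=200, repeats=25.
    """

    m: int = 2
    foreground: str = "dark"
    repeats: int = 5
    variant: str = "igwo"
    optimizer: IgwoConfig = field(
        default_factory=lambda: IgwoConfig(pop_size=20, max_iter=60))
    seed: int | None = None
    element: np.ndarray | None = None


def segment_lesion(img, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Full lesion segmentation: threshold -> fill -> open -> close -> largest CC.

    Returns a boolean mask; if morphology empties the foreground an empty
    mask is returned with a warning.
    """
    cfg = cfg if cfg is not None else SegmentationConfig()
    e = _check_element(cfg.element)
    th = find_thresholds(img, m=cfg.m, opt=cfg.optimizer, repeats=cfg.repeats,
                         variant=cfg.variant, seed=cfg.seed)
    labels = apply_thresholds(img, th)
    mask = lesion_mask_from_labels(labels, cfg.m, cfg.foreground)
    mask = fill_holes(mask, e)
    mask = open_mask(mask, e)
    mask = close_mask(mask, e)
    mask = largest_component(mask)
    if not mask.any():
        warnings.warn("segmentation produced an empty foreground", stacklevel=2)
    return mask


class KapurThresholder(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper: fit finds thresholds, transform labels pixels.

    ``fit(X)`` pools the histograms of the images in ``X`` (an ``(n, H, W)``
    or ``(n, H, W, 3)`` stack, or a single image) and runs the
    optimizer-driven Kapur search once; ``transform`` maps images to class
    label maps with the fitted thresholds.
    """

    def __init__(self, m: int = 2, repeats: int = 5, variant: str = "igwo",
                 pop_size: int = 20, max_iter: int = 60,
                 random_state: int | None = None):
        self.m = m
        self.repeats = repeats
        self.variant = variant
        self.pop_size = pop_size
        self.max_iter = max_iter
        self.random_state = random_state

    def _images(self, X) -> list[np.ndarray]:
        arr = np.asarray(X)
        if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] == 3):
            return [as_image(arr)]
        return [as_image(a) for a in arr]

    def fit(self, X, y=None):
        imgs = self._images(X)
        counts = np.zeros(256, dtype=np.int64)
        for img in imgs:
            counts += gray_histogram(img).counts
        hist = Histogram.from_counts(counts)
        cfg = IgwoConfig(pop_size=self.pop_size, max_iter=self.max_iter)
        tv, details = find_thresholds(
            hist, m=self.m, opt=cfg, repeats=self.repeats,
            variant=self.variant, seed=self.random_state, return_details=True)
        self.thresholds_ = tv
        self.entropy_ = details["entropy"]
        return self

    def transform(self, X):
        if not hasattr(self, "thresholds_"):
            raise AttributeError("KapurThresholder is not fitted")
        return np.stack([apply_thresholds(img, self.thresholds_)
                         for img in self._images(X)])
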