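"""Seeded generators for dermoscopy-like lesion images and optimizer benchmarks.

The generator emulates the salient structure of dermoscopic melanoma
screening collections: two-class lesion images with strong class imbalance,
occluding hair strokes, optional contrast compression, exact ground-truth
masks and patient grouping for leakage-free splits.

A lesion is a radially perturbed ellipse: the ellipse radius is modulated by
a low-order Fourier series (harmonics 3-8) scaled by the *irregularity*
amplitude, plus a first-harmonic *asymmetry* term.  The class difference is
encoded geometrically (irregularity/asymmetry) and in lesion texture variance
— both classes share the same mean lesion intensity, so a classifier must
learn shape and texture rather than a brightness threshold.

Everything is driven by ``numpy`` SeedSequences; per-record sub-seeds are
derived from (manifest seed, record index), so individual records regenerate
byte-identically.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from PIL import Image

from ._util import to_uint8

__all__ = [
    "LesionParams",
    "SyntheticManifest",
    "BENIGN_PARAMS",
    "MALIGNANT_PARAMS",
    "make_lesion_image",
    "add_hair",
    "make_classification_arrays",
    "make_dataset",
    "benchmark_function",
    "BenchmarkFunction",
]


@dataclass(frozen=True)
class LesionParams:
    """Generative parameters for one lesion image class.

    Intensities are 8-bit levels; geometric quantities are fractions of the
    image side.  ``irregularity`` is the standard deviation of the relative
    radial perturbation (capped at 0.5); ``contrast_compression`` in (0, 1]
    shrinks the dynamic range around mid-grey (1.0 = no compression).
    """

    size: int = 64
    background_mean: float = 180.0
    background_sigma: float = 6.0
    lesion_mean: float = 90.0
    lesion_sigma: float = 7.0
    axis_range: tuple[float, float] = (0.20, 0.32)
    irregularity: float = 0.08
    n_harmonics: tuple[int, int] = (3, 8)
    asymmetry: float = 0.05
    hair_count: int = 0
    hair_width: float = 2.0
    contrast_compression: float = 1.0
    min_margin: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.irregularity <= 0.5:
            raise ValueError("irregularity amplitude must lie in [0, 0.5]")
        if not 0.0 < self.contrast_compression <= 1.0:
            raise ValueError("contrast_compression must lie in (0, 1]")
        if self.background_mean - self.lesion_mean < self.min_margin:
            raise ValueError("lesion must be darker than the background by "
                             f"at least {self.min_margin} levels")
        if self.axis_range[1] >= 0.48:
            raise ValueError("lesion semi-axes must fit inside the image")


#: Benign-like lesions: smooth, symmetric, homogeneous texture.
BENIGN_PARAMS = LesionParams()
#: Malignant-like lesions: irregular borders, asymmetry, heterogeneous texture.
MALIGNANT_PARAMS = LesionParams(lesion_sigma=28.0, irregularity=0.32,
                                asymmetry=0.25)


@dataclass(frozen=True)
class SyntheticManifest:
    """Dataset manifest: records, imbalance ratio and the generating seed."""

    records: pd.DataFrame
    imbalance: float
    seed: int


def make_lesion_image(p: LesionParams, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One grayscale lesion image and its exact foreground mask."""
    s = p.size
    a = rng.uniform(*p.axis_range) * s
    b = rng.uniform(*p.axis_range) * s
    cy = s / 2.0 + rng.uniform(-0.04, 0.04) * s
    cx = s / 2.0 + rng.uniform(-0.04, 0.04) * s
    phi = rng.uniform(0.0, 2.0 * np.pi)
    k_lo, k_hi = p.n_harmonics
    ks = np.arange(k_lo, k_hi + 1)
    coefs = rng.standard_normal((2, ks.size))
    psi = rng.uniform(0.0, 2.0 * np.pi)

    yy, xx = np.mgrid[0:s, 0:s]
    dy = yy - cy
    dx = xx - cx
    # rotate into the ellipse frame
    ca, sa = np.cos(phi), np.sin(phi)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    theta = np.arctan2(v, u)
    r = np.hypot(u, v)
    # ellipse radius at each polar angle
    R = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if p.irregularity > 0:
        series = (coefs[0] @ np.cos(np.outer(ks, theta.ravel()))
                  + coefs[1] @ np.sin(np.outer(ks, theta.ravel())))
        series = series.reshape(theta.shape)
        series /= np.sqrt(coefs.size / 2.0)  # unit-variance normalisation
        rho = 1.0 + p.irregularity * series
    else:
        rho = np.ones_like(theta)
    rho = rho * (1.0 + p.asymmetry * np.cos(theta - psi))
    rho = np.clip(rho, 0.25, None)
    mask = r <= R * rho
    if R.max() * (1 + p.irregularity + p.asymmetry) > s / 2.0 + 2:
        raise ValueError("lesion does not fit inside the image")

    img = p.background_mean + p.background_sigma * rng.standard_normal((s, s))
    lesion = p.lesion_mean + p.lesion_sigma * rng.standard_normal((s, s))
    img[mask] = lesion[mask]
    c = p.contrast_compression
    if c < 1.0:
        img = 128.0 + c * (img - 128.0)
    return to_uint8(img), mask


def add_hair(img, count: int, width: float, rng: np.random.Generator,
             stroke_value: float = 35.0) -> tuple[np.ndarray, np.ndarray]:
    """Composite ``count`` dark anti-aliased arc strokes onto an image.

    Each stroke is a quadratic Bezier arc spanning a sizeable chord of the
    frame; a Euclidean distance transform of the densely sampled arc gives an
    alpha profile of full width ``width`` with a one-pixel anti-aliased
    falloff.  Returns the composited image and the exact stroke mask
    (alpha >= 0.5).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    arr = np.asarray(img, dtype=np.uint8)
    h, w = arr.shape[:2]
    alpha = np.zeros((h, w))
    for _ in range(count):
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.5, 1.0) * np.hypot(h, w) * 0.7
        p2 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
        mid = (p0 + p2) / 2.0
        perp = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
        nrm = np.linalg.norm(perp)
        if nrm > 0:
            perp = perp / nrm
        p1 = mid + perp * rng.uniform(-0.25, 0.25) * length
        ts = np.linspace(0.0, 1.0, max(64, int(3 * length)))[:, None]
        pts = ((1 - ts) ** 2 * p0 + 2 * (1 - ts) * ts * p1 + ts ** 2 * p2)
        inside = ((pts[:, 0] >= -0.5) & (pts[:, 0] <= h - 0.5)
                  & (pts[:, 1] >= -0.5) & (pts[:, 1] <= w - 0.5))
        iy = np.clip(np.round(pts[inside, 0]).astype(int), 0, h - 1)
        ix = np.clip(np.round(pts[inside, 1]).astype(int), 0, w - 1)
        stamp = np.ones((h, w), dtype=bool)
        stamp[iy, ix] = False
        if stamp.all():
            continue
        dist = ndi.distance_transform_edt(stamp)
        alpha = np.maximum(alpha, np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0))
    if arr.ndim == 3:
        out = (1 - alpha[..., None]) * arr + alpha[..., None] * stroke_value
    else:
        out = (1 - alpha) * arr + alpha * stroke_value
    mask = alpha >= 0.5
    return to_uint8(out), mask


def _record_rng(seed: int, index: int) -> np.random.Generator:
    """Per-record generator keyed by (manifest seed, record index)."""
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def make_classification_arrays(n_images: int, imbalance: float = 0.1,
                               n_patients: int = 50,
                               p_benign: LesionParams = BENIGN_PARAMS,
                               p_malignant: LesionParams = MALIGNANT_PARAMS,
                               seed: int = 0, hair: bool = False) -> dict:
    """Generate an in-memory labelled dataset.

    Returns a dict with ``images`` (n, s, s) uint8, ``masks`` (n, s, s) bool,
    ``labels`` ('benign'/'malignant'), ``patient_id`` and ``seed``.
    Malignant images are concentrated on a melanoma-prone subset of patients
    (roughly the imbalance fraction); benign images cycle over all patients.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if not 0.0 < imbalance < 1.0:
        raise ValueError("imbalance must lie in (0, 1)")
    if p_benign.size != p_malignant.size:
        raise ValueError("both classes must share the image size")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA55)))
    n_mal = int(round(n_images * imbalance))
    n_mal = min(max(n_mal, 1), n_images - 1)
    labels = np.array(["malignant"] * n_mal + ["benign"] * (n_images - n_mal))
    labels = labels[rng.permutation(n_images)]
    patients = np.array([f"P{i:04d}" for i in range(n_patients)])
    perm = rng.permutation(n_patients)
    # melanoma-prone patients contribute a couple of malignant images among
    # several benign ones, so the prone pool is about twice the image-level
    # malignant fraction
    n_mal_pat = max(1, int(round(n_patients * min(1.0, 2.0 * imbalance))))
    mal_pool = patients[perm[:n_mal_pat]]
    ben_pool = patients[perm]
    patient_id = np.empty(n_images, dtype=object)
    mi = bi = 0
    for i, lab in enumerate(labels):
        if lab == "malignant":
            patient_id[i] = mal_pool[mi % mal_pool.size]
            mi += 1
        else:
            patient_id[i] = ben_pool[bi % ben_pool.size]
            bi += 1
    size = p_benign.size
    images = np.empty((n_images, size, size), dtype=np.uint8)
    masks = np.empty((n_images, size, size), dtype=bool)
    for i, lab in enumerate(labels):
        p = p_malignant if lab == "malignant" else p_benign
        r = _record_rng(seed, i + 1)
        img, mask = make_lesion_image(p, r)
        if hair and p.hair_count > 0:
            img, _ = add_hair(img, p.hair_count, p.hair_width, r)
        images[i] = img
        masks[i] = mask
    return {"images": images, "masks": masks, "labels": labels,
            "patient_id": patient_id.astype(str), "seed": seed}


def make_dataset(n_images: int, imbalance: float, n_patients: int,
                 out_dir, p_benign: LesionParams = BENIGN_PARAMS,
                 p_malignant: LesionParams = MALIGNANT_PARAMS,
                 seed: int = 0, hair: bool = False) -> SyntheticManifest:
    """Write a synthetic dataset (PNG images + masks + manifest CSV) to disk.

    The manifest has columns ``image_path, mask_path, label, patient_id``.
    Regenerating with the same seed reproduces byte-identical files.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    data = make_classification_arrays(n_images, imbalance, n_patients,
                                      p_benign, p_malignant, seed, hair)
    rows = []
    for i in range(n_images):
        img_path = out / "images" / f"img_{i:05d}.png"
        mask_path = out / "masks" / f"mask_{i:05d}.png"
        Image.fromarray(data["images"][i]).save(img_path)
        Image.fromarray((data["masks"][i] * np.uint8(255))).save(mask_path)
        rows.append({"image_path": os.fspath(img_path),
                     "mask_path": os.fspath(mask_path),
                     "label": data["labels"][i],
                     "patient_id": data["patient_id"][i]})
    records = pd.DataFrame(rows)
    records.to_csv(out / "manifest.csv", index=False)
    return SyntheticManifest(records=records, imbalance=imbalance, seed=seed)


@dataclass(frozen=True)
class BenchmarkFunction:
    """Closed-form test objective with its known global minimum."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    optimum: np.ndarray
    optimum_value: float
    bounds: tuple[float, float]

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))


def _sphere(x):
    return (x ** 2).sum(axis=-1)


def _rastrigin(x):
    return 10.0 * x.shape[-1] + (x ** 2 - 10.0 * np.cos(2 * np.pi * x)).sum(axis=-1)


def _ackley(x):
    d = x.shape[-1]
    s1 = np.sqrt((x ** 2).sum(axis=-1) / d)
    s2 = np.cos(2 * np.pi * x).mean(axis=-1)
    return -20.0 * np.exp(-0.2 * s1) - np.exp(s2) + 20.0 + np.e


_BENCHMARKS = {
    "sphere": (_sphere, (-5.0, 5.0)),
    "rastrigin": (_rastrigin, (-5.12, 5.12)),
    "ackley": (_ackley, (-32.768, 32.768)),
}


def benchmark_function(name: str, dim: int) -> BenchmarkFunction:
    """Standard optimizer test function with its global minimum at the origin."""
    if dim < 1:
        raise ValueError("dim must be positive")
    try:
        fn, bounds = _BENCHMARKS[name]
    except KeyError:
        raise ValueError(f"unknown benchmark {name!r}; "
                         f"choose from {sorted(_BENCHMARKS)}") from None
    return BenchmarkFunction(name=name, fn=fn, optimum=np.zeros(dim),
                             optimum_value=0.0, bounds=bounds)
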