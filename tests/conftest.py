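"""Shared fixtures: synthetic histograms and lesion images."""
from __future__ import annotations

import numpy as np
import pytest

from igwoderm.segmentation import Histogram


def gaussian_mixture_histogram(modes, weights, sigmas, n=100_000, seed=0):
    """256-bin histogram of a quantized Gaussian mixture."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(modes), size=n, p=np.asarray(weights) / np.sum(weights))
    vals = np.clip(np.round(np.asarray(modes, float)[comp]
                            + np.asarray(sigmas, float)[comp]
                            * rng.standard_normal(n)), 0, 255).astype(int)
    return Histogram.from_counts(np.bincount(vals, minlength=256))


@pytest.fixture(scope="session")
def bimodal_hist():
    return gaussian_mixture_histogram([60, 180], [1, 2], [12, 15], seed=0)


@pytest.fixture(scope="session")
def benchmark_histograms():
    """Three histograms of increasing difficulty for threshold searches."""
    return [
        gaussian_mixture_histogram([60, 180], [1, 2], [12, 15], seed=0),
        gaussian_mixture_histogram([40, 120, 200], [1, 1, 1], [10, 14, 12], seed=1),
        gaussian_mixture_histogram([90, 170], [3, 1], [20, 10], seed=2),
    ]
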