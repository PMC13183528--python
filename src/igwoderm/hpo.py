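"""IGWO-driven hyperparameter search over (f1, f2, f3, d).

The search space is 4-dimensional and mixed: three integer filter counts in
[16, 256] and a continuous dropout rate in [0.2, 0.8].  The objective is the
validation loss of the CNN trained with the fixed protocol on a
patient-grouped stratified subset of the training split (default 15%), so a
candidate evaluation is a full (desk-scale) training run.  Fitness values are
cached per decoded candidate — elite copies produced by the regeneration step
are exact duplicates and cost nothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._util import round_half_up
from .classifier import (CNNClassifier, CNNHyperparams, DROPOUT_BOUNDS,
                         FILTER_BOUNDS)
from .optimizer import IgwoConfig, SearchSpace, optimize

__all__ = [
    "HpoConfig",
    "HpoResult",
    "hyperparameter_space",
    "decode_candidate",
    "hpo_objective",
    "search_hyperparameters",
]


def hyperparameter_space() -> SearchSpace:
    """The 4-dim mixed search space matching :class:`CNNHyperparams` bounds."""
    return SearchSpace(
        lower=[FILTER_BOUNDS[0]] * 3 + [DROPOUT_BOUNDS[0]],
        upper=[FILTER_BOUNDS[1]] * 3 + [DROPOUT_BOUNDS[1]],
        integer_mask=[True, True, True, False],
    )


def decode_candidate(x) -> CNNHyperparams:
    """Decode an optimizer position: round the filter dims, keep d continuous."""
    x = np.asarray(x, dtype=float)
    f = np.clip(round_half_up(x[:3]), *FILTER_BOUNDS).astype(int)
    d = float(np.clip(x[3], *DROPOUT_BOUNDS))
    return CNNHyperparams(f1=int(f[0]), f2=int(f[1]), f3=int(f[2]), d=d)


@dataclass(frozen=True)
class HpoConfig:
    """Search settings.

    Defaults are desk scale (tiny images, few epochs, short optimizer runs);
    the full-scale protocol is N=30, T=200, 50 epochs per candidate at
    225x225.
    """

    optimizer: IgwoConfig = field(
        default_factory=lambda: IgwoConfig(pop_size=30, max_iter=10))
    fitness_subset_fraction: float = 0.15
    epochs_per_candidate: int = 5
    batch_size: int = 32
    patience: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fitness_subset_fraction <= 1.0:
            raise ValueError("fitness_subset_fraction must lie in (0, 1]")
        if self.epochs_per_candidate < 1:
            raise ValueError("epochs_per_candidate must be positive")


@dataclass
class HpoResult:
    """Best candidate, its fitness and the evaluated-candidate trace."""

    best: CNNHyperparams
    best_fitness: float
    trace: list


def _training_subset(X, y, patients, fraction, rng):
    """Patient-grouped, class-stratified subset of the training data."""
    y = np.asarray(y)
    patients = np.asarray(patients)
    uniq = np.unique(patients)
    pat_mal = {p: (y[patients == p] == "malignant").any() for p in uniq}
    order = uniq[rng.permutation(uniq.size)]
    chosen, n_target = [], int(np.ceil(fraction * len(y)))
    count = 0
    # take malignant-bearing patients first so the subset keeps both classes
    for p in sorted(order, key=lambda q: not pat_mal[q]):
        chosen.append(p)
        count += int((patients == p).sum())
        if count >= n_target and len(chosen) >= 2:
            mask = np.isin(patients, chosen)
            if (y[mask] == "malignant").any() and (y[mask] == "benign").any():
                break
    mask = np.isin(patients, chosen)
    return mask


def hpo_objective(h: CNNHyperparams, data: dict, cfg: HpoConfig) -> float:
    """Validation loss of the CNN built for ``h`` under the fixed protocol.

    ``data`` is a dict with ``X_train, y_train, X_val, y_val`` and optionally
    ``patients_train`` (enables the patient-grouped fitness subset).
    Deterministic for a given configuration seed.
    """
    rng = np.random.default_rng(cfg.seed)
    X, y = data["X_train"], np.asarray(data["y_train"])
    if "patients_train" in data and cfg.fitness_subset_fraction < 1.0:
        mask = _training_subset(X, y, data["patients_train"],
                                cfg.fitness_subset_fraction, rng)
        X, y = X[mask], y[mask]
    clf = CNNClassifier(filters=h.filters, dropout=h.d,
                        batch_size=cfg.batch_size,
                        epochs=cfg.epochs_per_candidate, patience=cfg.patience,
                        random_state=cfg.seed)
    try:
        clf.fit(X, y, validation_data=(data["X_val"], data["y_val"]))
    except Exception as exc:  # propagate with candidate identity
        raise RuntimeError(f"training failed for candidate {h}") from exc
    vl = clf.history_["val_loss"]
    return float(min(vl)) if vl else float("inf")


def search_hyperparameters(data, cfg: HpoConfig | None = None,
                           objective: Callable[[CNNHyperparams], float] | None = None,
                           variant: str = "igwo") -> HpoResult:
    """Run IGWO over the mixed 4-dim space.

    ``objective`` overrides the default trained-CNN fitness (used for
    surrogate objectives and testing); it receives a decoded
    :class:`CNNHyperparams`.  The trace records every cache-missing
    evaluation as ``(hyperparams, fitness)``; duplicated candidates are
    served from the cache and never re-trained.
    """
    cfg = cfg if cfg is not None else HpoConfig()
    if cfg.optimizer.max_iter < 1 or cfg.optimizer.pop_size < 4:
        raise ValueError("optimizer budget must be positive")
    if objective is None:
        if data is None:
            raise ValueError("data is required unless an objective is supplied")
        objective = lambda h: hpo_objective(h, data, cfg)  # noqa: E731
    cache: dict = {}
    trace: list = []

    def fitness(x):
        h = decode_candidate(x)
        key = (h.f1, h.f2, h.f3, round(h.d, 12))
        if key not in cache:
            val = float(objective(h))
            cache[key] = val
            trace.append((h, val))
        return cache[key]

    opt_cfg = cfg.optimizer if cfg.optimizer.seed is not None else replace(
        cfg.optimizer, seed=cfg.seed)
    res = optimize(fitness, hyperparameter_space(), opt_cfg, variant=variant)
    best = decode_candidate(res.best_position)
    return HpoResult(best=best, best_fitness=float(res.best_fitness), trace=trace)
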