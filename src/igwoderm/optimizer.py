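"""Grey wolf optimisation over box-bounded, optionally integer, search spaces.

The grey wolf optimizer (GWO) is a population metaheuristic that mimics the
hunting hierarchy of a wolf pack.  The three best solutions found so far are
retained as the *alpha*, *beta* and *delta* wolves; every agent moves to the
average of three pulls, one towards each elite::

    D_e     = |C * x_e - x|
    x'_e    = x_e - A * D_e          for e in {alpha, beta, delta}
    x(t+1)  = (x'_alpha + x'_beta + x'_delta) / 3

with one pair of coefficient vectors per agent per dimension, shared by the
three elite pulls: ``A = 2*a*r1 - a`` and ``C = 2*r2`` where
``r1, r2 ~ U[0, 1)`` and the control scalar ``a = 2*(1 - t/T)`` decays
linearly from 2 to 0, shifting the pack from exploration to exploitation.

The improved variant (IGWO) adds *fitness-based omega regeneration*: each
iteration the pack is ranked, the worst ``floor(r*N)`` omega wolves are
eliminated and each is regenerated either as a copy of an elite (probability
``p``, elite drawn with rank-proportional weights) or as a Gaussian resample
around the alpha wolf with decaying scale ``sigma = 1/(t+1)``.  Resamples are
evaluated immediately so the decaying probe around alpha can refine the
elites; regenerated wolves carry no greedy memory (their first move is always
accepted), which keeps the pack from freezing onto duplicated elites.

All objectives are minimised; negate a maximisation objective at the call
site.  Integer dimensions are handled by rounding to the nearest integer at
evaluation time; stored positions stay continuous so sub-integer gradient
information survives between iterations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "SearchSpace",
    "Population",
    "EliteTriple",
    "GwoCoefficients",
    "IgwoConfig",
    "OptResult",
    "ObjectiveError",
    "init_population",
    "gwo_coefficients",
    "gwo_step",
    "igwo_regenerate",
    "optimize",
]


class ObjectiveError(ValueError):
    """Raised when the objective returns a non-finite value."""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box, optionally with integer-valued dimensions.

    Parameters
    ----------
    lower, upper:
        Per-dimension bounds with ``lower[i] < upper[i]``.
    integer_mask:
        Boolean per dimension; ``True`` dimensions are rounded to the
        nearest integer at objective evaluation (stored positions stay
        continuous).  Integer dimensions must have integer-valued bounds.
    """

    lower: np.ndarray
    upper: np.ndarray
    integer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        if self.integer_mask is None:
            mask = np.zeros(lower.size, dtype=bool)
        else:
            mask = np.atleast_1d(np.asarray(self.integer_mask, dtype=bool))
            if mask.shape != lower.shape:
                raise ValueError("integer_mask length must match the bounds")
        if mask.any():
            for b in (lower[mask], upper[mask]):
                if not np.all(b == np.floor(b)):
                    raise ValueError("integer dimensions require integer-valued bounds")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "integer_mask", mask)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def quantize(self, x: np.ndarray) -> np.ndarray:
        """Clip to the box and round integer dimensions (half-up)."""
        out = self.clip(np.asarray(x, dtype=float))
        if self.integer_mask.any():
            out = np.array(out, copy=True)
            out[..., self.integer_mask] = _round_half_up(out[..., self.integer_mask])
        return out

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pts = rng.uniform(self.lower, self.upper, size=(n, self.dim))
        return self.quantize(pts)


@dataclass
class Population:
    """Positions and fitness of the wolf pack.

    ``fitness`` is NaN for agents that have not been evaluated yet (freshly
    moved or Gaussian-regenerated agents).
    """

    positions: np.ndarray
    fitness: np.ndarray
    iteration: int = 0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Population":
        return Population(self.positions.copy(), self.fitness.copy(), self.iteration)


@dataclass
class EliteTriple:
    """The three best solutions found so far (alpha <= beta <= delta)."""

    alpha: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    alpha_fit: float = np.inf
    beta_fit: float = np.inf
    delta_fit: float = np.inf

    @classmethod
    def empty(cls, dim: int) -> "EliteTriple":
        z = np.zeros(dim)
        return cls(z.copy(), z.copy(), z.copy())

    def absorb(self, positions: np.ndarray, fitness: np.ndarray) -> None:
        """Update the triple from a batch of evaluated agents.

        Agents are scanned in index order with strict comparisons, so equal
        fitness never displaces an incumbent (deterministic tie-breaking) and
        an agent is never stored twice.  NaN fitness entries are skipped.
        """
        for x, f in zip(positions, fitness):
            if np.isnan(f):
                continue
            f = float(f)
            if f < self.alpha_fit:
                self.delta, self.delta_fit = self.beta, self.beta_fit
                self.beta, self.beta_fit = self.alpha, self.alpha_fit
                self.alpha, self.alpha_fit = x.copy(), f
            elif f < self.beta_fit and (f > self.alpha_fit or np.isinf(self.beta_fit)):
                self.delta, self.delta_fit = self.beta, self.beta_fit
                self.beta, self.beta_fit = x.copy(), f
            elif f < self.delta_fit and (f > self.beta_fit or np.isinf(self.delta_fit)):
                self.delta, self.delta_fit = x.copy(), f

    def stack(self) -> tuple[np.ndarray, np.ndarray]:
        pos = np.stack([self.alpha, self.beta, self.delta])
        fit = np.array([self.alpha_fit, self.beta_fit, self.delta_fit])
        return pos, fit


@dataclass(frozen=True)
class GwoCoefficients:
    """Per-agent coefficient vectors shared by the three elite pulls."""

    a: float
    A: np.ndarray
    C: np.ndarray
    r1: np.ndarray
    r2: np.ndarray


def gwo_coefficients(t: int, max_iter: int, rng: np.random.Generator,
                     shape: tuple[int, ...]) -> GwoCoefficients:
    """Draw the A and C vectors for one move at iteration ``t``.

    ``r1`` is drawn before ``r2``; this draw order is part of the public
    contract so results can be reproduced step by step.
    """
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration index {t} outside [0, {max_iter}]")
    a = 2.0 * (1.0 - t / max_iter)
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    return GwoCoefficients(a=a, A=2.0 * a * r1 - a, C=2.0 * r2, r1=r1, r2=r2)


@dataclass(frozen=True)
class IgwoConfig:
    """Optimizer settings.

    ``elim_fraction`` (r) and ``elite_prob`` (p) only matter for the IGWO
    variant.  ``elite_weights`` give the rank-proportional selection weights
    for alpha:beta:delta when an eliminated omega is replaced by an elite
    copy.  With ``greedy_memory`` each agent keeps the better of its old and
    new position after every move.
    """

    pop_size: int = 30
    max_iter: int = 200
    elim_fraction: float = 0.3
    elite_prob: float = 0.7
    elite_weights: tuple[float, float, float] = (3.0, 2.0, 1.0)
    seed: int | None = None
    greedy_memory: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be at least 4 (three elites plus omegas)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not 0.0 < self.elim_fraction <= 1.0:
            raise ValueError("elim_fraction must lie in (0, 1]")
        if not 0.0 <= self.elite_prob <= 1.0:
            raise ValueError("elite_prob must lie in [0, 1]")
        w = np.asarray(self.elite_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("elite_weights must be three non-negative weights")


@dataclass
class OptResult:
    """Best solution, best fitness, per-iteration best trace and call count."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    n_evaluations: int

    def to_csv(self, path) -> None:
        """Write the convergence trace as ``iteration,best_fitness``."""
        with open(path, "w") as fh:
            fh.write("iteration,best_fitness\n")
            for i, v in enumerate(self.history):
                fh.write(f"{i},{v!r}\n")


def init_population(space: SearchSpace, config: IgwoConfig,
                    rng: np.random.Generator) -> Population:
    """Place ``pop_size`` wolves uniformly in the box (integer dims rounded)."""
    positions = space.sample(rng, config.pop_size)
    fitness = np.full(config.pop_size, np.nan)
    return Population(positions=positions, fitness=fitness, iteration=0)


def gwo_step(pop: Population, elites: EliteTriple, t: int, max_iter: int,
             rng: np.random.Generator, space: SearchSpace) -> Population:
    """Move every agent to the mean of the three elite-guided pulls.

    One coefficient pair per agent per dimension (``r1`` drawn before ``r2``,
    see :func:`gwo_coefficients`) is shared by the alpha, beta and delta
    pulls, matching the single A/C pair of the update equations.  The result
    is clipped to the box; integer dimensions are rounded at evaluation, not
    here.
    """
    X = pop.positions
    co = gwo_coefficients(t, max_iter, rng, X.shape)
    acc = np.zeros_like(X)
    for e_pos in (elites.alpha, elites.beta, elites.delta):
        D = np.abs(co.C * e_pos - X)
        acc += e_pos - co.A * D
    new_pos = space.clip(acc / 3.0)
    return Population(positions=new_pos,
                      fitness=np.full(pop.n_agents, np.nan),
                      iteration=t + 1)


def _regenerate(pop: Population, elites: EliteTriple, config: IgwoConfig,
                t: int, rng: np.random.Generator, space: SearchSpace
                ) -> tuple[Population, list, list]:
    """Core of the omega regeneration; also reports which rows became elite
    copies and which became Gaussian resamples."""
    if np.isnan(pop.fitness).any():
        raise ValueError("igwo_regenerate requires fitness evaluated for all agents")
    n = pop.n_agents
    k = min(int(np.floor(config.elim_fraction * n)), n - 3)
    out = pop.copy()
    copies: list = []
    resamples: list = []
    if k <= 0:
        return out, copies, resamples
    order = np.argsort(pop.fitness, kind="stable")  # ties broken by agent index
    worst = order[n - k:]
    elite_pos, elite_fit = elites.stack()
    weights = np.asarray(config.elite_weights, dtype=float)
    weights = weights / weights.sum()
    sigma = 1.0 / (t + 1)
    for i in worst:
        if rng.random() < config.elite_prob:
            j = rng.choice(3, p=weights)
            out.positions[i] = elite_pos[j]
            out.fitness[i] = elite_fit[j]
            copies.append(int(i))
        else:
            cand = elites.alpha + sigma * rng.standard_normal(space.dim)
            out.positions[i] = space.clip(cand)
            out.fitness[i] = np.nan
            resamples.append(int(i))
    return out, copies, resamples


def igwo_regenerate(pop: Population, elites: EliteTriple, config: IgwoConfig,
                    t: int, rng: np.random.Generator,
                    space: SearchSpace) -> Population:
    """Eliminate the worst ``floor(r*N)`` omegas and regenerate them.

    Each eliminated agent becomes, with probability ``p``, an exact copy of
    one elite (drawn with weights ``elite_weights``, inheriting the elite's
    known fitness), otherwise ``alpha + sigma*g`` with ``g ~ N(0, I)`` and
    ``sigma = 1/(t+1)``; resamples are marked unevaluated (NaN fitness).
    The replacement count is capped at ``N - 3`` so the three elites are
    never eliminated.
    """
    out, _, _ = _regenerate(pop, elites, config, t, rng, space)
    return out


def _evaluate(objective: Callable, X: np.ndarray, vectorized: bool,
              space: SearchSpace | None = None) -> np.ndarray:
    if space is not None:
        X = space.quantize(X)  # integer dims are rounded at evaluation
    if vectorized:
        vals = np.asarray(objective(X), dtype=float)
        if vals.shape != (X.shape[0],):
            raise ValueError("vectorized objective must return one value per row")
    else:
        vals = np.array([float(objective(x)) for x in X])
    bad = ~np.isfinite(vals)
    if bad.any():
        i = int(np.argmax(bad))
        raise ObjectiveError(
            f"objective returned non-finite value {vals[i]} at position {X[i]}")
    return vals


def optimize(objective: Callable, space: SearchSpace,
             config: IgwoConfig | None = None, variant: str = "igwo",
             vectorized: bool = False) -> OptResult:
    """Run GWO or IGWO on a minimisation objective.

    Parameters
    ----------
    objective:
        Maps a position vector to a finite scalar.  With ``vectorized=True``
        it instead maps an ``(N, dim)`` matrix to ``N`` values (much faster
        for cheap objectives such as histogram entropies).
    variant:
        ``"gwo"`` for the canonical algorithm, ``"igwo"`` to add fitness-based
        omega regeneration.

    Returns
    -------
    OptResult with the best-ever position, its fitness, the length ``T+1``
    best-fitness trace and the number of objective evaluations — ``N*(T+1)``
    for GWO, plus one evaluation per Gaussian resample for IGWO.
    """
    if variant not in ("gwo", "igwo"):
        raise ValueError(f"unknown variant {variant!r}; expected 'gwo' or 'igwo'")
    config = config if config is not None else IgwoConfig()
    rng = np.random.default_rng(config.seed)
    pop = init_population(space, config, rng)
    pop.fitness = _evaluate(objective, pop.positions, vectorized, space)
    n_eval = pop.n_agents
    elites = EliteTriple.empty(space.dim)
    elites.absorb(pop.positions, pop.fitness)
    history = [elites.alpha_fit]
    for t in range(config.max_iter):
        cand = gwo_step(pop, elites, t, config.max_iter, rng, space)
        cand.fitness = _evaluate(objective, cand.positions, vectorized, space)
        n_eval += cand.n_agents
        if config.greedy_memory:
            # keep the better of old/new per agent; agents without a memory
            # (freshly regenerated wolves) always accept the move
            accept = np.isnan(pop.fitness) | (cand.fitness < pop.fitness)
            pop = Population(
                positions=np.where(accept[:, None], cand.positions, pop.positions),
                fitness=np.where(accept, cand.fitness, pop.fitness),
                iteration=t + 1,
            )
        else:
            pop = cand
        elites.absorb(pop.positions, pop.fitness)
        if variant == "igwo":
            pop, copies, resamples = _regenerate(pop, elites, config, t, rng,
                                                 space)
            # Gaussian resamples are evaluated right away: the decaying
            # sigma = 1/(t+1) probe around alpha is the regeneration's
            # exploitation mechanism and must be able to refine the elites
            if resamples:
                vals = _evaluate(objective, pop.positions[resamples],
                                 vectorized, space)
                pop.fitness[resamples] = vals
                n_eval += len(resamples)
                elites.absorb(pop.positions[resamples], vals)
            # regenerated wolves carry no greedy memory: elite copies would
            # otherwise freeze at the elite and drain the pack's diversity
            pop.fitness[copies] = np.nan
        history.append(elites.alpha_fit)
    return OptResult(best_position=space.quantize(elites.alpha),
                     best_fitness=float(elites.alpha_fit),
                     history=np.asarray(history),
                     n_evaluations=n_eval)
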