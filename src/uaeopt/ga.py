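"""Real-coded genetic algorithm for multi-response process optimization.

The objective ("fitness") scalarizes the four surrogate-model predictions
as a weighted sum of min–max-normalized responses,

    FF(x) = sum_k  weight_k * (yhat_k(x) − L_k) / (U_k − L_k),

maximized over the factor box constraints.  With unit weights and L/U set
to the observed response ranges the fitness lives on a 0–4 scale, 4 being
"every response simultaneously at its best observed value".

The GA is a standard elitist real-coded scheme: tournament selection,
blend (BLX-α) crossover, per-gene Gaussian mutation clipped to the box,
and an archive of the top distinct individuals encountered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "FitnessSpec",
    "GAConfig",
    "OptimizationResult",
    "fitness",
    "optimize",
    "optimize_models",
    "DEFAULT_FACTOR_BOUNDS",
]

#: Box constraints of the extraction factors: ultrasonication power (W),
#: temperature (°C), DES molar ratio (–), DES water content (%).
DEFAULT_FACTOR_BOUNDS: tuple[tuple[float, float], ...] = (
    (100.0, 300.0),
    (30.0, 70.0),
    (0.5, 2.5),
    (15.0, 35.0),
)


@dataclass(frozen=True)
class FitnessSpec:
    """Normalization bounds, weights and factor box for the fitness."""

    response_bounds: tuple[tuple[float, float], ...]
    weights: tuple[float, ...] | None = None
    factor_bounds: tuple[tuple[float, float], ...] = DEFAULT_FACTOR_BOUNDS

    def __post_init__(self) -> None:
        for lo, hi in self.response_bounds:
            if not hi > lo:
                raise ValueError("response upper bound must exceed lower bound")
        w = self.weights
        if w is not None:
            if len(w) != len(self.response_bounds):
                raise ValueError("one weight per response required")
            if any(wi < 0 for wi in w):
                raise ValueError("weights must be non-negative")

    @classmethod
    def from_observed(
        cls,
        observed,
        weights: Sequence[float] | None = None,
        factor_bounds: Sequence[tuple[float, float]] = DEFAULT_FACTOR_BOUNDS,
    ) -> "FitnessSpec":
        """Normalization bounds from the observed min/max of each response
        column of a response table (DataFrame)."""
        bounds = tuple(
            (float(observed[c].min()), float(observed[c].max()))
            for c in observed.columns
        )
        return cls(
            response_bounds=bounds,
            weights=tuple(weights) if weights is not None else None,
            factor_bounds=tuple(tuple(b) for b in factor_bounds),
        )


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 200
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    mutation_scale: float = 0.1  # × factor range
    tournament_size: int = 3
    elites: int = 2
    archive_size: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be at least 4")
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("at least one generation required")


@dataclass
class OptimizationResult:
    """Best point found, its fitness, and the solution archive."""

    best_point: np.ndarray
    best_fitness: float
    predicted_responses: np.ndarray | None
    archive: list[tuple[np.ndarray, float]] = field(default_factory=list)
    config: GAConfig = GAConfig()


def fitness(models: Mapping[str, object], x, spec: FitnessSpec) -> float:
    """Weighted sum of min–max-normalized model predictions at point x."""
    x = np.asarray(x, dtype=float)
    for v, (lo, hi) in zip(x, spec.factor_bounds):
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise ValueError(f"point {x} violates factor bounds")
    weights = spec.weights or (1.0,) * len(spec.response_bounds)
    total = 0.0
    for w, (lo, hi), model in zip(weights, spec.response_bounds, models.values()):
        yhat = float(np.asarray(model.predict(x[None, :]))[0])
        total += w * (yhat - lo) / (hi - lo)
    return total


def _predict_all(models: Mapping[str, object], x: np.ndarray) -> np.ndarray:
    return np.array(
        [float(np.asarray(m.predict(x[None, :]))[0]) for m in models.values()]
    )


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: GAConfig = GAConfig(),
    models: Mapping[str, object] | None = None,
) -> OptimizationResult:
    """Maximize a scalar objective over a box with a real-coded GA.

    ``objective`` receives one point (1-D array in factor units) and
    returns its fitness.  Every evaluated individual is clipped to the
    box, the running best is preserved by elitism, and the top
    ``archive_size`` distinct individuals (pairwise separated by more
    than 1e−6 in range-normalized units) are archived.

    When ``models`` is given, the predicted responses at the best point
    are attached to the result.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("degenerate bounds")
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    d = lo.size

    pop = lo + rng.random((config.population, d)) * span
    fit = np.array([objective(ind) for ind in pop])

    # archive of (point, fitness), distinct in normalized coordinates
    archive: list[tuple[np.ndarray, float]] = []

    def archive_push(point: np.ndarray, f: float) -> None:
        near = [i for i, (p, _) in enumerate(archive)
                if np.linalg.norm((p - point) / span) <= 1e-6]
        if near:
            if f <= max(archive[i][1] for i in near):
                return
            for i in reversed(near):
                del archive[i]
        archive.append((point.copy(), f))
        archive.sort(key=lambda pf: -pf[1])
        del archive[config.archive_size:]

    for ind, f in zip(pop, fit):
        archive_push(ind, f)

    def tournament() -> np.ndarray:
        idx = rng.integers(0, config.population, size=config.tournament_size)
        return pop[idx[np.argmax(fit[idx])]]

    for _ in range(config.generations):
        elite_idx = np.argsort(fit)[::-1][: config.elites]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.population:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_prob:
                # BLX-0.5 blend: sample uniformly on the interval extended
                # by half its width on each side
                c_lo = np.minimum(p1, p2)
                c_hi = np.maximum(p1, p2)
                w = c_hi - c_lo
                child = rng.uniform(c_lo - 0.5 * w, c_hi + 0.5 * w + 1e-300)
            else:
                child = p1.copy()
            mutate = rng.random(d) < config.mutation_prob
            noise = rng.normal(0.0, config.mutation_scale * span, size=d)
            child = np.where(mutate, child + noise, child)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fit = np.array([objective(ind) for ind in pop])
        for ind, f in zip(pop, fit):
            archive_push(ind, f)

    best_point, best_fitness = archive[0]
    return OptimizationResult(
        best_point=best_point.copy(),
        best_fitness=float(best_fitness),
        predicted_responses=(
            _predict_all(models, best_point) if models is not None else None
        ),
        archive=[(p.copy(), float(f)) for p, f in archive],
        config=config,
    )


def optimize_models(
    models: Mapping[str, object],
    spec: FitnessSpec,
    config: GAConfig = GAConfig(),
) -> OptimizationResult:
    """GA maximization of the multi-response fitness of trained surrogates."""
    return optimize(
        lambda x: fitness(models, x, spec), spec.factor_bounds, config, models
    )
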