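"""Trigonometric Differential Evolution (TDE) for box-constrained minimisation.

TDE is classic DE/rand/1/bin augmented with an occasional *trigonometric
mutation*: with probability Mt the mutant is built from the centroid of three
population members, perturbed along their pairwise differences with weights
proportional to their objective magnitudes, which biases the move towards the
best of the three.  Otherwise the standard differential mutation
v = x_r1 + F (x_r2 - x_r3) is used.  Binomial crossover with constant CR and
greedy one-to-one selection complete a generation, so the per-generation best
objective is non-increasing by construction.

Defaults follow common practice for this family of optimisers: F = 0.99,
CR = 0.85, Mt = 0.05, population size NP = 200.  Out-of-bounds trial
components are reflected back into the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["TDEConfig", "OptimisationTrace", "OptimiseResult", "optimise", "step"]

Objective = Callable[[np.ndarray], float]


@dataclass
class TDEConfig:
    """Operating parameters and stopping rule for one TDE run."""

    bounds: Sequence[tuple[float, float]]
    F: float = 0.99
    CR: float = 0.85
    Mt: float = 0.05
    NP: int = 200
    max_generations: int = 250
    seed: int = 0
    #: stop early if the best objective improves by less than ``stall_tol``
    #: over this many consecutive generations (None disables the check)
    stall_generations: int | None = None
    stall_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        if not self.bounds:
            raise ValueError("at least one dimension required")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"each bound needs low < high, got ({lo}, {hi})")
        if self.NP < 4:
            raise ValueError("population size NP must be >= 4")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must be in [0, 1]")
        if not 0.0 <= self.Mt <= 1.0:
            raise ValueError("Mt must be in [0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def dimensions(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds])


@dataclass
class OptimisationTrace:
    """Best objective after initialisation and after each generation."""

    best_objective: np.ndarray
    n_evaluations: int
    n_generations: int


@dataclass
class OptimiseResult:
    x: np.ndarray
    fun: float
    trace: OptimisationTrace


def _reflect(trial: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Fold out-of-box components back inside by reflection at the walls."""
    for _ in range(8):
        below = trial < lower
        above = trial > upper
        if not (below.any() or above.any()):
            return trial
        trial = np.where(below, 2.0 * lower - trial, trial)
        trial = np.where(above, 2.0 * upper - trial, trial)
    return np.clip(trial, lower, upper)  # pathological overshoot


def step(
    population: np.ndarray,
    fitness: np.ndarray,
    objective: Objective,
    config: TDEConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Advance one generation; returns (population, fitness, evaluations).

    Greedy selection guarantees each survivor is no worse than its
    predecessor.  Mutates nothing: new arrays are returned.
    """
    n, dims = population.shape
    lower, upper = config.lower, config.upper
    new_pop = population.copy()
    new_fit = fitness.copy()
    for i in range(n):
        r1, r2, r3 = _distinct_indices(rng, n, i)
        x1, x2, x3 = population[r1], population[r2], population[r3]
        if rng.random() < config.Mt:
            f1, f2, f3 = abs(fitness[r1]), abs(fitness[r2]), abs(fitness[r3])
            total = f1 + f2 + f3
            centroid = (x1 + x2 + x3) / 3.0
            if total > 0.0:
                p1, p2, p3 = f1 / total, f2 / total, f3 / total
                mutant = (
                    centroid
                    + (p2 - p1) * (x1 - x2)
                    + (p3 - p2) * (x2 - x3)
                    + (p1 - p3) * (x3 - x1)
                )
            else:
                mutant = centroid
        else:
            mutant = x1 + config.F * (x2 - x3)
        cross = rng.random(dims) < config.CR
        cross[rng.integers(dims)] = True
        trial = np.where(cross, mutant, population[i])
        trial = _reflect(trial, lower, upper)
        f_trial = float(objective(trial))
        if f_trial <= fitness[i]:
            new_pop[i] = trial
            new_fit[i] = f_trial
    return new_pop, new_fit, n


def _distinct_indices(rng: np.random.Generator, n: int, i: int) -> tuple[int, int, int]:
    out: list[int] = []
    while len(out) < 3:
        r = int(rng.integers(n))
        if r != i and r not in out:
            out.append(r)
    return out[0], out[1], out[2]


def optimise(objective: Objective, config: TDEConfig) -> OptimiseResult:
    """Minimise ``objective`` over the configured box.

    Reproducible: the same config (including seed) yields a bit-identical
    trajectory.  The returned trace holds the best objective after
    initialisation and after every generation (non-increasing).
    """
    rng = np.random.default_rng(config.seed)
    lower, upper = config.lower, config.upper
    population = rng.uniform(lower, upper, size=(config.NP, config.dimensions))
    fitness = np.array([float(objective(x)) for x in population])
    evaluations = config.NP
    best_trace = [float(fitness.min())]

    generations = 0
    for _ in range(config.max_generations):
        population, fitness, n_eval = step(population, fitness, objective, config, rng)
        evaluations += n_eval
        generations += 1
        best_trace.append(float(fitness.min()))
        if config.stall_generations is not None and generations >= config.stall_generations:
            window = config.stall_generations
            if best_trace[-1 - window] - best_trace[-1] <= config.stall_tol:
                break

    best_index = int(np.argmin(fitness))
    trace = OptimisationTrace(
        best_objective=np.asarray(best_trace),
        n_evaluations=evaluations,
        n_generations=generations,
    )
    return OptimiseResult(x=population[best_index].copy(), fun=float(fitness[best_index]), trace=trace)
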