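"""Shared machinery for the population metaheuristics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SolutionVector", "Bounds", "evaluate", "write_run_log"]


@dataclass
class SolutionVector:
    """A point in a bounded d-dimensional search space with attached fitness.

    Fitness follows the minimization convention (lower is better);
    ``+inf`` marks an unevaluated or failed solution.
    """

    values: np.ndarray
    fitness: float = math.inf

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def copy(self) -> "SolutionVector":
        return SolutionVector(self.values.copy(), self.fitness)


@dataclass
class Bounds:
    """Componentwise box constraints ``lb <= x <= ub``."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape:
            raise ValueError("lb and ub must have the same shape")
        if np.any(self.lb > self.ub):
            raise ValueError("every lb must be <= ub")

    @property
    def dimension(self) -> int:
        return self.lb.size

    @classmethod
    def cube(cls, lb: float, ub: float, d: int) -> "Bounds":
        return cls(np.full(d, lb), np.full(d, ub))

    @classmethod
    def unit(cls, d: int) -> "Bounds":
        return cls.cube(0.0, 1.0, d)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.lb + rng.random(self.dimension) * (self.ub - self.lb)


def evaluate(fitness, values: np.ndarray) -> float:
    """Evaluate ``fitness`` at ``values``; non-finite results become ``+inf``."""
    f = float(fitness(values))
    if not math.isfinite(f):
        warnings.warn(
            f"fitness returned non-finite value {f!r}; recording +inf", stacklevel=2
        )
        return math.inf
    return f


def write_run_log(path, history_rows) -> None:
    """Write the per-iteration run log.

    CSV columns: iteration, best_fitness, mean_fitness, mutation_fired.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "best_fitness", "mean_fitness", "mutation_fired"])
        for row in history_rows:
            writer.writerow(row)
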