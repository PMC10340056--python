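"""Coati Optimization Algorithm (COA).

A two-phase population metaheuristic for bound-constrained minimization.
In the hunting phase, the first half of the population "climbs" toward the
best solution so far (the iguana), while the second half reacts to a
randomly grounded iguana — approaching it if it is better than they are,
retreating otherwise. In the escape phase every agent makes a local move
inside a neighborhood whose bounds shrink as ``1/t`` over the run. Every
candidate is accepted only if strictly better (greedy), so stored fitness
never increases.

Draw-order contract (mirrored by the scalar-oracle tests):

* climb: ``r`` (d draws), then ``I`` (d draws, uniform on {1, 2})
* grounded iguana: ``r`` (d draws), evaluated once per iteration
* ground coati: ``r`` (d draws) always; ``I`` (d draws) only on the
  approach branch
* escape: one ``r`` per dimension, reused in both places of the formula
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Bounds, SolutionVector, evaluate

__all__ = [
    "COAConfig",
    "COAState",
    "coa_climb_step",
    "coa_ground_iguana",
    "coa_ground_step",
    "greedy_accept",
    "coa_local_bounds",
    "coa_escape_step",
    "coa_iterate",
    "coa_optimize",
]


@dataclass
class COAConfig:
    population_size: int
    iterations: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2 (both halves non-empty)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class COAState:
    agents: list[SolutionVector]
    best_ever: SolutionVector
    bounds: Bounds
    config: COAConfig
    rng: np.random.Generator
    t: int = 0


def coa_climb_step(
    agent: SolutionVector,
    iguana: SolutionVector,
    bounds: Bounds,
    rng: np.random.Generator,
) -> SolutionVector:
    """Tree-climbing move toward the iguana (population best).

    ``candidate_j = x_j + r_j * (Iguana_j - I_j * x_j)`` with fresh
    ``r ~ U(0,1)`` and ``I in {1, 2}`` per dimension.
    """
    x = agent.values
    r = rng.random(x.size)
    big_i = rng.integers(1, 3, x.size).astype(float)
    return SolutionVector(bounds.clip(x + r * (iguana.values - big_i * x)))


def coa_ground_iguana(bounds: Bounds, rng: np.random.Generator) -> SolutionVector:
    """Drop the iguana at a uniformly random position in the box."""
    return SolutionVector(bounds.sample(rng))


def coa_ground_step(
    agent: SolutionVector,
    iguana_g: SolutionVector,
    bounds: Bounds,
    rng: np.random.Generator,
) -> SolutionVector:
    """Ground-coati move relative to the grounded iguana.

    Approaches the grounded iguana when it is strictly fitter than the
    agent, retreats from it otherwise. Both ``iguana_g`` and ``agent``
    must carry evaluated fitness values.
    """
    x = agent.values
    r = rng.random(x.size)
    if iguana_g.fitness < agent.fitness:
        big_i = rng.integers(1, 3, x.size).astype(float)
        cand = x + r * (iguana_g.values - big_i * x)
    else:
        cand = x + r * (x - iguana_g.values)
    return SolutionVector(bounds.clip(cand))


def greedy_accept(
    agent: SolutionVector, candidate: SolutionVector
) -> SolutionVector:
    """Keep the candidate iff it is strictly fitter; ties keep the agent."""
    return candidate if candidate.fitness < agent.fitness else agent


def coa_local_bounds(bounds: Bounds, t: int) -> Bounds:
    """Escape-phase neighborhood: global bounds scaled by ``1/t``."""
    if t < 1:
        raise ValueError("iteration counter must be >= 1")
    return Bounds(bounds.lb / t, bounds.ub / t)


def coa_escape_step(
    agent: SolutionVector,
    local: Bounds,
    bounds: Bounds,
    rng: np.random.Generator,
) -> SolutionVector:
    """Predator-escape move inside the shrinking local neighborhood.

    ``candidate_j = x_j + (1 - 2 r_j) * (lb_j^local + r_j * (ub_j^local -
    lb_j^local))``, one ``r_j`` per dimension; clipped to the global box.
    """
    x = agent.values
    r = rng.random(x.size)
    offset = (1.0 - 2.0 * r) * (local.lb + r * (local.ub - local.lb))
    return SolutionVector(bounds.clip(x + offset))


def init_state(fitness, bounds: Bounds, config: COAConfig) -> COAState:
    rng = np.random.default_rng(config.seed)
    agents = []
    for _ in range(config.population_size):
        sol = SolutionVector(bounds.sample(rng))
        sol.fitness = evaluate(fitness, sol.values)
        agents.append(sol)
    best = min(agents, key=lambda a: a.fitness).copy()
    return COAState(agents=agents, best_ever=best, bounds=bounds, config=config, rng=rng)


def _accept(state: COAState, i: int, cand: SolutionVector, fitness) -> None:
    cand.fitness = evaluate(fitness, cand.values)
    state.agents[i] = greedy_accept(state.agents[i], cand)
    if state.agents[i].fitness < state.best_ever.fitness:
        state.best_ever = state.agents[i].copy()


def coa_iterate(state: COAState, fitness) -> COAState:
    """One COA iteration: hunting phase then escape phase (in place)."""
    cfg = state.config
    bounds = state.bounds
    rng = state.rng
    state.t += 1
    half = cfg.population_size // 2

    # hunting phase: climbers chase the best-so-far iguana
    for i in range(half):
        cand = coa_climb_step(state.agents[i], state.best_ever, bounds, rng)
        _accept(state, i, cand, fitness)

    # a grounded iguana appears at a random spot; ground coatis react
    iguana_g = coa_ground_iguana(bounds, rng)
    iguana_g.fitness = evaluate(fitness, iguana_g.values)
    for i in range(half, cfg.population_size):
        cand = coa_ground_step(state.agents[i], iguana_g, bounds, rng)
        _accept(state, i, cand, fitness)

    # escape phase: local moves within 1/t-shrunk bounds
    local = coa_local_bounds(bounds, state.t)
    for i in range(cfg.population_size):
        cand = coa_escape_step(state.agents[i], local, bounds, rng)
        _accept(state, i, cand, fitness)
    return state


def coa_optimize(
    fitness, bounds: Bounds, config: COAConfig, *, log: list | None = None
) -> tuple[SolutionVector, list[float]]:
    """Minimize ``fitness`` over the box; returns (best, per-iteration bests)."""
    if bounds.dimension == 0:
        raise ValueError("search space must have at least one dimension")
    state = init_state(fitness, bounds, config)
    history: list[float] = []
    for _ in range(config.iterations):
        coa_iterate(state, fitness)
        history.append(state.best_ever.fitness)
        if log is not None:
            mean_fit = float(np.mean([a.fitness for a in state.agents]))
            log.append((state.t, state.best_ever.fitness, mean_fit, 0))
    return state.best_ever, history
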