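"""Al-Biruni Earth Radius (BER) optimization.

A population metaheuristic for bound-constrained minimization. The
population is split into an exploration subgroup, which perturbs agents by
a circle-diameter step derived from the Earth-radius formula
``r = h * cos(x) / (1 - cos(x))``, and an exploitation subgroup, which
either moves toward the population leader or samples around the best
solution so far. The best-ever solution is retained (elitism); when the
best fitness stalls for a configurable number of iterations, the
exploration subgroup is regenerated by a mutation operator to escape local
optima.

All randomness flows through a single :class:`numpy.random.Generator`, so
runs are reproducible per seed. Draw order within each step is part of the
contract (tests transcribe it against scalar oracles):

* exploration: ``r1`` (d draws), then ``r2`` (d draws)
* exploitation: one uniform coin, then either ``r2``/``r3`` (d draws each,
  toward-leader) or ``z``, ``h``, ``x`` (scalars, around-leader)
* mutation: per dimension ``z``, ``h``, ``x``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .base import Bounds, SolutionVector, evaluate

__all__ = [
    "BERConfig",
    "BERState",
    "ber_radius",
    "exploration_step",
    "exploit_toward_leader",
    "exploit_around_leader",
    "mutation_step",
    "ber_iterate",
    "ber_optimize",
]

_COS_TOL = 1e-12


@dataclass
class BERConfig:
    """Settings for a BER run.

    ``exploration_fraction`` of the population explores; the rest exploits.
    ``stagnation_window`` consecutive iterations with best-fitness
    improvement below ``stagnation_tol`` trigger the mutation operator.
    """

    population_size: int
    iterations: int
    exploration_fraction: float = 0.5
    stagnation_window: int = 3
    stagnation_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.exploration_fraction < 1.0:
            raise ValueError("exploration_fraction must lie in (0, 1)")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be >= 1")

    @property
    def n_explore(self) -> int:
        """Exploration-group size; both groups keep at least one agent."""
        n = round(self.exploration_fraction * self.population_size)
        return min(max(n, 1), self.population_size - 1)


@dataclass
class BERState:
    agents: list[SolutionVector]
    best_ever: SolutionVector
    bounds: Bounds
    config: BERConfig
    rng: np.random.Generator
    t: int = 0
    stagnation_counter: int = 0
    mutation_fired: bool = False


def ber_radius(h: float, x_deg: float, *, tol: float = _COS_TOL) -> float:
    """Earth-radius step factor ``h * cos(x) / (1 - cos(x))``.

    ``h`` is a random scalar in [0, 2] and ``x`` an angle in degrees with
    ``0 < x <= 180``. Raises for angles where ``cos(x)`` is 1 within
    tolerance (division by zero).
    """
    if not 0.0 < x_deg <= 180.0:
        raise ValueError(f"angle must lie in (0, 180], got {x_deg}")
    c = math.cos(math.radians(x_deg))
    if abs(1.0 - c) < tol:
        raise ValueError(f"angle {x_deg} deg has cos(x) == 1 within tolerance")
    return h * c / (1.0 - c)


def _draw_radius(rng: np.random.Generator) -> float:
    """Draw ``h ~ U(0,2)`` and ``x ~ U(0,180)`` (resampling degenerate angles)."""
    h = 2.0 * rng.random()
    while True:
        x = 180.0 * rng.random()
        if x > 0.0 and abs(1.0 - math.cos(math.radians(x))) >= _COS_TOL:
            return ber_radius(h, x)


def exploration_step(
    agent: SolutionVector, bounds: Bounds, rng: np.random.Generator
) -> SolutionVector:
    """Perturb an exploration agent around its current position.

    The step is ``S + D * (2 r2 - 1)`` with diameter ``D = r1 * (S - 1)``
    (elementwise); the candidate is clipped to the box and returned
    unevaluated.
    """
    s = agent.values
    r1 = rng.random(s.size)
    r2 = rng.random(s.size)
    d = r1 * (s - 1.0)
    return SolutionVector(bounds.clip(s + d * (2.0 * r2 - 1.0)))


def exploit_toward_leader(
    agent: SolutionVector,
    leader: SolutionVector,
    bounds: Bounds,
    rng: np.random.Generator,
) -> SolutionVector:
    """Move an exploitation agent toward the leader.

    ``candidate = r2 * (S + D)`` with ``D = r3 * (L - S)`` elementwise.
    """
    s = agent.values
    r2 = rng.random(s.size)
    r3 = rng.random(s.size)
    d = r3 * (leader.values - s)
    return SolutionVector(bounds.clip(r2 * (s + d)))


def exploit_around_leader(
    best: SolutionVector,
    t: int,
    n_iterations: int,
    bounds: Bounds,
    rng: np.random.Generator,
) -> SolutionVector:
    """Sample the region surrounding the best solution.

    ``candidate = r * (S* + k)`` with ``k = z + 2 t^2 / N^2`` (scalar,
    growing over the run) and ``r`` the Earth-radius factor.
    """
    if n_iterations == 0:
        raise ValueError("iteration budget must be positive")
    if not 0 <= t <= n_iterations:
        raise ValueError(f"t={t} outside [0, {n_iterations}]")
    z = rng.random()
    r = _draw_radius(rng)
    k = z + 2.0 * t * t / (n_iterations * n_iterations)
    return SolutionVector(bounds.clip(r * (best.values + k)))


def mutation_step(
    t: int, n_iterations: int, bounds: Bounds, rng: np.random.Generator
) -> SolutionVector:
    """Generate a fresh agent independent of any current position.

    Per dimension: ``k * z^2 - h cos(x)/(1 - cos(x))`` with fresh draws of
    ``z``, ``h``, ``x`` and ``k = z + 2 t^2 / N^2`` reusing that
    dimension's ``z``.
    """
    if n_iterations == 0:
        raise ValueError("iteration budget must be positive")
    out = np.empty(bounds.dimension)
    for j in range(bounds.dimension):
        z = rng.random()
        r = _draw_radius(rng)
        k = z + 2.0 * t * t / (n_iterations * n_iterations)
        out[j] = k * z * z - r
    return SolutionVector(bounds.clip(out))


def init_state(fitness, bounds: Bounds, config: BERConfig) -> BERState:
    """Draw and evaluate the initial population."""
    rng = np.random.default_rng(config.seed)
    agents = []
    for _ in range(config.population_size):
        sol = SolutionVector(bounds.sample(rng))
        sol.fitness = evaluate(fitness, sol.values)
        agents.append(sol)
    best = min(agents, key=lambda a: a.fitness).copy()
    return BERState(agents=agents, best_ever=best, bounds=bounds, config=config, rng=rng)


def ber_iterate(state: BERState, fitness) -> BERState:
    """Advance the population by one BER iteration (in place).

    Exploration agents take an exploration step; exploitation agents flip a
    fair coin between the toward-leader and around-leader moves. Every
    candidate is accepted only if strictly better (greedy). The stagnation
    counter increments when the best fitness improves by less than the
    tolerance; on reaching the window, exploration agents are regenerated by
    mutation and the counter resets.
    """
    cfg = state.config
    bounds = state.bounds
    rng = state.rng
    state.t += 1
    state.mutation_fired = False
    prev_best = state.best_ever.fitness
    n_explore = cfg.n_explore

    for i, agent in enumerate(state.agents):
        if i < n_explore:
            cand = exploration_step(agent, bounds, rng)
        else:
            if rng.random() < 0.5:
                cand = exploit_toward_leader(agent, state.best_ever, bounds, rng)
            else:
                cand = exploit_around_leader(
                    state.best_ever, state.t, cfg.iterations, bounds, rng
                )
        cand.fitness = evaluate(fitness, cand.values)
        if cand.fitness < agent.fitness:
            state.agents[i] = cand
        if state.agents[i].fitness < state.best_ever.fitness:
            state.best_ever = state.agents[i].copy()

    if prev_best - state.best_ever.fitness < cfg.stagnation_tol:
        state.stagnation_counter += 1
    else:
        state.stagnation_counter = 0

    if state.stagnation_counter >= cfg.stagnation_window:
        for i in range(n_explore):
            mutant = mutation_step(state.t, cfg.iterations, bounds, rng)
            mutant.fitness = evaluate(fitness, mutant.values)
            state.agents[i] = mutant
            if mutant.fitness < state.best_ever.fitness:
                state.best_ever = mutant.copy()
        state.stagnation_counter = 0
        state.mutation_fired = True
    return state


def ber_optimize(
    fitness, bounds: Bounds, config: BERConfig, *, log: list | None = None
) -> tuple[SolutionVector, list[float]]:
    """Minimize ``fitness`` over the box; returns (best, per-iteration bests).

    ``log`` (optional) collects run-log rows
    ``(iteration, best_fitness, mean_fitness, mutation_fired)``.
    """
    if bounds.dimension == 0:
        raise ValueError("search space must have at least one dimension")
    state = init_state(fitness, bounds, config)
    history: list[float] = []
    for _ in range(config.iterations):
        ber_iterate(state, fitness)
        history.append(state.best_ever.fitness)
        if log is not None:
            mean_fit = float(np.mean([a.fitness for a in state.agents]))
            log.append((state.t, state.best_ever.fitness, mean_fit, int(state.mutation_fired)))
    return state.best_ever, history
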