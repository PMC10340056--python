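"""Scalar transcription oracles for the two optimizers.

Each function replays one full optimizer iteration with plain-Python
scalar arithmetic, equation by equation, consuming the identical random
stream as the vectorized implementation. They are used to verify
full-iteration equivalence and must stay independent of the
implementation modules.
"""

import math

import numpy as np


def ber_oracle_one_iteration(seed: int, pop: int, d: int, lb: float, ub: float,
                             n_iterations: int, fitness):
    """Init + one BER iteration; returns (agent positions, agent fits, best fit).

    Assumes exploration fraction 0.5 (first half explores) and that the
    first iteration runs at t = 1.
    """
    rng = np.random.default_rng(seed)
    span = ub - lb
    agents = []
    for _ in range(pop):
        r = rng.random(d)
        pos = [lb + rj * span for rj in r]
        agents.append([pos, fitness(pos)])
    best = min(agents, key=lambda a: a[1])
    best = [list(best[0]), best[1]]
    n_explore = min(max(round(0.5 * pop), 1), pop - 1)

    def clip(v):
        return [min(max(x, lb), ub) for x in v]

    def accept(i, cand):
        nonlocal best
        fc = fitness(cand)
        if fc < agents[i][1]:
            agents[i] = [cand, fc]
        if agents[i][1] < best[1]:
            best = [list(agents[i][0]), agents[i][1]]

    for i in range(pop):
        s = agents[i][0]
        if i < n_explore:
            r1 = rng.random(d)
            r2 = rng.random(d)
            cand = [s[j] + r1[j] * (s[j] - 1.0) * (2.0 * r2[j] - 1.0) for j in range(d)]
        else:
            coin = rng.random()
            if coin < 0.5:
                r2 = rng.random(d)
                r3 = rng.random(d)
                cand = [r2[j] * (s[j] + r3[j] * (best[0][j] - s[j])) for j in range(d)]
            else:
                z = rng.random()
                h = 2.0 * rng.random()
                while True:
                    x = 180.0 * rng.random()
                    if x > 0 and abs(1.0 - math.cos(math.radians(x))) >= 1e-12:
                        break
                r = h * math.cos(math.radians(x)) / (1.0 - math.cos(math.radians(x)))
                k = z + 2.0 / (n_iterations * n_iterations)
                cand = [r * (best[0][j] + k) for j in range(d)]
        accept(i, clip(cand))
    return [a[0] for a in agents], [a[1] for a in agents], best[1]


def coa_oracle_one_iteration(seed: int, pop: int, d: int, lb: float, ub: float,
                             fitness):
    """Init + one COA iteration (t = 1); returns (positions, fits, best fit)."""
    rng = np.random.default_rng(seed)
    span = ub - lb
    agents = []
    for _ in range(pop):
        r = rng.random(d)
        pos = [lb + rj * span for rj in r]
        agents.append([pos, fitness(pos)])
    best = min(agents, key=lambda a: a[1])
    best = [list(best[0]), best[1]]
    half = pop // 2

    def clip(v):
        return [min(max(x, lb), ub) for x in v]

    def accept(i, cand):
        nonlocal best
        fc = fitness(cand)
        if fc < agents[i][1]:
            agents[i] = [cand, fc]
        if agents[i][1] < best[1]:
            best = [list(agents[i][0]), agents[i][1]]

    for i in range(half):
        x = agents[i][0]
        r = rng.random(d)
        big_i = rng.integers(1, 3, d)
        accept(i, clip([x[j] + r[j] * (best[0][j] - big_i[j] * x[j]) for j in range(d)]))
    rg = rng.random(d)
    ig = [lb + rj * span for rj in rg]
    fig = fitness(ig)
    for i in range(half, pop):
        x = agents[i][0]
        r = rng.random(d)
        if fig < agents[i][1]:
            big_i = rng.integers(1, 3, d)
            cand = [x[j] + r[j] * (ig[j] - big_i[j] * x[j]) for j in range(d)]
        else:
            cand = [x[j] + r[j] * (x[j] - ig[j]) for j in range(d)]
        accept(i, clip(cand))
    for i in range(pop):  # escape phase, t = 1: local box == global box
        x = agents[i][0]
        r = rng.random(d)
        accept(i, clip([x[j] + (1 - 2 * r[j]) * (lb + r[j] * (ub - lb)) for j in range(d)]))
    return [a[0] for a in agents], [a[1] for a in agents], best[1]
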