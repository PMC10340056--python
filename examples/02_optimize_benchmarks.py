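"""Run both metaheuristics on the sphere benchmark.

Minimizes f(x) = sum(x^2) over [-5, 5]^5 with the Earth-radius (BER) and
coati (COA) optimizers and prints the best-fitness trajectory. Both
histories are non-increasing by construction (elitism / greedy
acceptance); the final value should be orders of magnitude below the
initial population's best.
"""

import numpy as np

from histotune import BERConfig, Bounds, COAConfig, ber_optimize, coa_optimize


def sphere(x):
    return float(np.sum(x * x))


bounds = Bounds.cube(-5.0, 5.0, 5)

for name, run in [
    ("BER", lambda: ber_optimize(sphere, bounds, BERConfig(20, 100, seed=1))),
    ("COA", lambda: coa_optimize(sphere, bounds, COAConfig(20, 100, seed=1))),
]:
    best, history = run()
    marks = [history[i] for i in (0, 9, 49, 99)]
    print(f"{name}: best fitness at iterations 1/10/50/100 -> "
          + " ".join(f"{v:.3e}" for v in marks))
    print(f"{name}: final best point {np.round(best.values, 6)}")
# Each printed value is the lowest fitness seen so far; convergence toward
# zero shows the optimizer locating the sphere's global minimum at the origin.
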