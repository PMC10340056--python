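"""Coati optimizer: step formulas, greedy acceptance, shrinking bounds."""

import math

import numpy as np
import pytest

from histotune.optimizers import (
    Bounds,
    COAConfig,
    SolutionVector,
    coa_climb_step,
    coa_escape_step,
    coa_ground_iguana,
    coa_ground_step,
    coa_local_bounds,
    coa_optimize,
    greedy_accept,
)
from histotune.optimizers.coa import coa_iterate, init_state


def sphere(x):
    return float(np.sum(x * x))


class _FixedRng:
    def __init__(self, uniforms, ints=()):
        self._u = list(uniforms)
        self._i = list(ints)

    def random(self, size=None):
        if size is None:
            return self._u.pop(0)
        return np.array([self._u.pop(0) for _ in range(size)])

    def integers(self, low, high, size=None):
        if size is None:
            return self._i.pop(0)
        return np.array([self._i.pop(0) for _ in range(size)])


BOX = Bounds.cube(-10.0, 10.0, 2)


class TestClimbStep:
    def test_zero_r_is_identity(self):
        agent = SolutionVector(np.array([3.0, -2.0]), 5.0)
        iguana = SolutionVector(np.array([0.0, 0.0]), 0.0)
        cand = coa_climb_step(agent, iguana, BOX, _FixedRng([0.0, 0.0], [1, 2]))
        np.testing.assert_allclose(cand.values, agent.values)

    def test_agent_at_iguana_with_unit_i_is_fixed(self):
        pos = np.array([1.5, -0.5])
        agent = SolutionVector(pos.copy(), 1.0)
        iguana = SolutionVector(pos.copy(), 1.0)
        cand = coa_climb_step(agent, iguana, BOX, _FixedRng([0.7, 0.3], [1, 1]))
        np.testing.assert_allclose(cand.values, pos)

    def test_matches_scalar_oracle(self):
        agent = SolutionVector(np.array([2.0, -3.0]), 13.0)
        iguana = SolutionVector(np.array([0.5, 0.5]), 0.5)
        cand = coa_climb_step(agent, iguana, BOX, np.random.default_rng(21))
        rng = np.random.default_rng(21)
        r = rng.random(2)
        big_i = rng.integers(1, 3, 2)
        expected = [
            x + rj * (ig - ij * x)
            for x, ig, rj, ij in zip(agent.values, iguana.values, r, big_i)
        ]
        np.testing.assert_allclose(cand.values, np.clip(expected, -10, 10), atol=1e-12)


class TestGroundIguana:
    def test_extremes_hit_bounds(self):
        lo = coa_ground_iguana(BOX, _FixedRng([0.0, 0.0]))
        hi = coa_ground_iguana(BOX, _FixedRng([1.0, 1.0]))
        np.testing.assert_allclose(lo.values, BOX.lb)
        np.testing.assert_allclose(hi.values, BOX.ub)

    def test_degenerate_box_dimension(self):
        b = Bounds(np.array([2.0, -1.0]), np.array([2.0, 1.0]))
        pos = coa_ground_iguana(b, np.random.default_rng(0))
        assert pos.values[0] == 2.0


class TestGroundStep:
    def test_zero_r_identity_on_approach_branch(self):
        agent = SolutionVector(np.array([1.0, 1.0]), 2.0)
        good = SolutionVector(np.array([0.0, 0.0]), 0.0)
        cand = coa_ground_step(agent, good, BOX, _FixedRng([0.0, 0.0], [1, 2]))
        np.testing.assert_allclose(cand.values, agent.values)

    def test_retreat_from_itself_is_identity(self):
        pos = np.array([2.0, -2.0])
        agent = SolutionVector(pos.copy(), 8.0)
        bad = SolutionVector(pos.copy(), 9.0)  # not fitter -> retreat branch
        cand = coa_ground_step(agent, bad, BOX, _FixedRng([0.9, 0.4]))
        np.testing.assert_allclose(cand.values, pos)

    @pytest.mark.parametrize("iguana_fit,branch", [(0.0, "approach"), (99.0, "retreat")])
    def test_both_branches_match_scalar_oracle(self, iguana_fit, branch):
        agent = SolutionVector(np.array([3.0, -1.0]), 10.0)
        ig = SolutionVector(np.array([-2.0, 2.0]), iguana_fit)
        cand = coa_ground_step(agent, ig, BOX, np.random.default_rng(5))
        rng = np.random.default_rng(5)
        r = rng.random(2)
        if branch == "approach":
            big_i = rng.integers(1, 3, 2)
            expected = [
                x + rj * (g - ij * x)
                for x, g, rj, ij in zip(agent.values, ig.values, r, big_i)
            ]
        else:
            expected = [
                x + rj * (x - g) for x, g, rj in zip(agent.values, ig.values, r)
            ]
        np.testing.assert_allclose(cand.values, np.clip(expected, -10, 10), atol=1e-12)


class TestGreedyAcceptance:
    def test_better_candidate_kept(self):
        a = SolutionVector(np.zeros(2), 5.0)
        c = SolutionVector(np.ones(2), 3.0)
        assert greedy_accept(a, c) is c

    def test_worse_candidate_rejected(self):
        a = SolutionVector(np.zeros(2), 3.0)
        c = SolutionVector(np.ones(2), 5.0)
        assert greedy_accept(a, c) is a

    def test_tie_keeps_incumbent(self):
        a = SolutionVector(np.zeros(2), 5.0)
        c = SolutionVector(np.ones(2), 5.0)
        assert greedy_accept(a, c) is a


class TestLocalBounds:
    def test_t1_equals_global(self):
        local = coa_local_bounds(BOX, 1)
        np.testing.assert_allclose(local.lb, BOX.lb)
        np.testing.assert_allclose(local.ub, BOX.ub)

    def test_exact_division(self):
        local = coa_local_bounds(BOX, 2)
        np.testing.assert_allclose(local.lb, [-5.0, -5.0])
        np.testing.assert_allclose(local.ub, [5.0, 5.0])

    def test_monotone_shrink(self):
        widths = [coa_local_bounds(BOX, t).ub[0] - coa_local_bounds(BOX, t).lb[0]
                  for t in range(1, 8)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_t_zero_rejected(self):
        with pytest.raises(ValueError):
            coa_local_bounds(BOX, 0)


class TestEscapeStep:
    def test_r_half_is_identity(self):
        agent = SolutionVector(np.array([4.0, -4.0]), 32.0)
        cand = coa_escape_step(agent, coa_local_bounds(BOX, 2), BOX, _FixedRng([0.5, 0.5]))
        np.testing.assert_allclose(cand.values, agent.values)

    def test_r_zero_adds_local_lower_bound(self):
        agent = SolutionVector(np.array([1.0, 2.0]), 5.0)
        local = coa_local_bounds(BOX, 5)  # (-2, 2)
        cand = coa_escape_step(agent, local, BOX, _FixedRng([0.0, 0.0]))
        np.testing.assert_allclose(cand.values, agent.values + local.lb)

    def test_matches_scalar_oracle(self):
        agent = SolutionVector(np.array([1.0, -2.0]), 5.0)
        local = coa_local_bounds(BOX, 3)
        cand = coa_escape_step(agent, local, BOX, np.random.default_rng(13))
        rng = np.random.default_rng(13)
        r = rng.random(2)
        expected = [
            x + (1 - 2 * rj) * (lb + rj * (ub - lb))
            for x, rj, lb, ub in zip(agent.values, r, local.lb, local.ub)
        ]
        np.testing.assert_allclose(cand.values, np.clip(expected, -10, 10), atol=1e-12)


class TestIterateAndOptimize:
    def test_full_iteration_matches_scalar_transcription(self):
        """One iteration on 4 agents, d=2, transcribed step by step."""
        bounds = Bounds.cube(-5.0, 5.0, 2)
        config = COAConfig(population_size=4, iterations=6, seed=31)
        state = init_state(sphere, bounds, config)
        coa_iterate(state, sphere)

        rng = np.random.default_rng(31)
        agents = []
        for _ in range(4):
            r = rng.random(2)
            pos = [-5.0 + rj * 10.0 for rj in r]
            agents.append([pos, pos[0] ** 2 + pos[1] ** 2])
        best = min(agents, key=lambda a: a[1])
        best = [list(best[0]), best[1]]

        def clip(v):
            return [min(max(x, -5.0), 5.0) for x in v]

        def accept(i, cand):
            nonlocal best
            fc = cand[0] ** 2 + cand[1] ** 2
            if fc < agents[i][1]:
                agents[i] = [cand, fc]
            if agents[i][1] < best[1]:
                best = [list(agents[i][0]), agents[i][1]]

        # phase 1: climbers (agents 0, 1) chase the best-so-far
        for i in range(2):
            x = agents[i][0]
            r = rng.random(2)
            big_i = rng.integers(1, 3, 2)
            accept(i, clip([x[j] + r[j] * (best[0][j] - big_i[j] * x[j]) for j in range(2)]))
        # grounded iguana
        rg = rng.random(2)
        ig = [-5.0 + rj * 10.0 for rj in rg]
        fig = ig[0] ** 2 + ig[1] ** 2
        for i in range(2, 4):
            x = agents[i][0]
            r = rng.random(2)
            if fig < agents[i][1]:
                big_i = rng.integers(1, 3, 2)
                cand = [x[j] + r[j] * (ig[j] - big_i[j] * x[j]) for j in range(2)]
            else:
                cand = [x[j] + r[j] * (x[j] - ig[j]) for j in range(2)]
            accept(i, clip(cand))
        # phase 2: escape within bounds/t, t = 1
        lb_l, ub_l = -5.0, 5.0
        for i in range(4):
            x = agents[i][0]
            r = rng.random(2)
            accept(i, clip([
                x[j] + (1 - 2 * r[j]) * (lb_l + r[j] * (ub_l - lb_l)) for j in range(2)
            ]))

        for impl, oracle in zip(state.agents, agents):
            np.testing.assert_allclose(impl.values, oracle[0], atol=1e-12)
            assert impl.fitness == pytest.approx(oracle[1], abs=1e-12)
        assert state.best_ever.fitness == pytest.approx(best[1], abs=1e-12)

    def test_agent_fitness_never_increases(self):
        bounds = Bounds.cube(-5, 5, 3)
        state = init_state(sphere, bounds, COAConfig(6, 10, seed=2))
        before = [a.fitness for a in state.agents]
        for _ in range(10):
            coa_iterate(state, sphere)
            after = [a.fitness for a in state.agents]
            assert all(b2 <= b1 for b1, b2 in zip(before, after))
            before = after

    def test_history_non_increasing_and_deterministic(self):
        bounds = Bounds.cube(-5, 5, 4)
        cfg = COAConfig(8, 25, seed=17)
        _, h1 = coa_optimize(sphere, bounds, cfg)
        _, h2 = coa_optimize(sphere, bounds, cfg)
        assert h1 == h2
        assert len(h1) == 25
        assert all(a >= b for a, b in zip(h1, h1[1:]))

    def test_population_of_one_rejected(self):
        with pytest.raises(ValueError):
            COAConfig(1, 5)

    def test_non_finite_fitness_recorded_as_inf(self):
        with pytest.warns(UserWarning):
            best, _ = coa_optimize(lambda x: float("inf"), Bounds.cube(-1, 1, 2),
                                   COAConfig(4, 2, seed=0))
        assert math.isinf(best.fitness)


class TestSphereConvergence:
    def test_reduces_sphere_by_two_orders(self):
        """d=5, pop 20, 200 iterations: <=1% of the initial best, >=18/20 seeds."""
        bounds = Bounds.cube(-5.0, 5.0, 5)
        hits = 0
        for seed in range(20):
            cfg = COAConfig(20, 200, seed=seed)
            f0 = init_state(sphere, bounds, cfg).best_ever.fitness
            best, hist = coa_optimize(sphere, bounds, cfg)
            assert all(a >= b for a, b in zip(hist, hist[1:]))
            if best.fitness <= 0.01 * f0:
                hits += 1
        assert hits >= 18
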