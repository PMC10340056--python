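"""Earth-radius optimizer: step formulas, elitism, stagnation, convergence."""

import math

import numpy as np
import pytest

from histotune.optimizers import (
    BERConfig,
    Bounds,
    SolutionVector,
    ber_optimize,
    ber_radius,
    exploit_around_leader,
    exploit_toward_leader,
    exploration_step,
    mutation_step,
)
from histotune.optimizers.ber import ber_iterate, init_state

WIDE = Bounds.cube(-100.0, 100.0, 3)


class TestRadiusFormula:
    def test_right_angle_zeroes_numerator(self):
        assert ber_radius(1.3, 90.0) == pytest.approx(0.0, abs=1e-15)

    def test_straight_angle_closed_form(self):
        # h * (-1) / (1 - (-1)) = -h/2
        assert ber_radius(2.0, 180.0) == pytest.approx(-1.0)

    def test_matches_hand_evaluation(self):
        # frozen from an independent scalar evaluation of h*cos(x)/(1-cos(x))
        # at h=0.7, x=60 deg: 0.7*0.5/0.5 = 0.7
        assert ber_radius(0.7, 60.0) == pytest.approx(0.7, abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, -5.0, 181.0])
    def test_rejects_out_of_range_angles(self, x):
        with pytest.raises(ValueError):
            ber_radius(1.0, x)

    def test_rejects_degenerate_cosine(self):
        with pytest.raises(ValueError):
            ber_radius(1.0, 1e-9)


class _FixedRng:
    """Replays a scripted sequence of uniform draws."""

    def __init__(self, seq):
        self._seq = list(seq)

    def random(self, size=None):
        if size is None:
            return self._seq.pop(0)
        return np.array([self._seq.pop(0) for _ in range(size)])


class TestStepOperators:
    def test_exploration_is_identity_when_r2_is_half(self):
        agent = SolutionVector(np.array([2.0, -1.0, 0.5]))
        rng = _FixedRng([0.3, 0.9, 0.1, 0.5, 0.5, 0.5])  # r1 then r2
        cand = exploration_step(agent, WIDE, rng)
        np.testing.assert_allclose(cand.values, agent.values)

    def test_exploration_is_identity_at_all_ones(self):
        # S = 1 zeroes the diameter regardless of the draws
        agent = SolutionVector(np.ones(3))
        cand = exploration_step(agent, WIDE, np.random.default_rng(0))
        np.testing.assert_allclose(cand.values, agent.values)

    def test_exploration_matches_scalar_oracle(self):
        agent = SolutionVector(np.array([0.4, -2.0, 3.0]))
        rng = np.random.default_rng(42)
        cand = exploration_step(agent, WIDE, rng)
        oracle_rng = np.random.default_rng(42)
        r1 = oracle_rng.random(3)
        r2 = oracle_rng.random(3)
        expected = [
            s + r1j * (s - 1.0) * (2.0 * r2j - 1.0)
            for s, r1j, r2j in zip(agent.values, r1, r2)
        ]
        np.testing.assert_allclose(cand.values, expected, atol=1e-12)

    def test_toward_leader_identity_when_step_vanishes(self):
        agent = SolutionVector(np.array([1.5, -0.5]))
        leader = SolutionVector(np.array([0.0, 0.0]), 0.0)
        rng = _FixedRng([1.0, 1.0, 0.0, 0.0])  # r2 = 1, r3 = 0
        cand = exploit_toward_leader(agent, leader, Bounds.cube(-10, 10, 2), rng)
        np.testing.assert_allclose(cand.values, agent.values)

    def test_toward_leader_reaches_leader_from_leader(self):
        leader = SolutionVector(np.array([0.7, -0.2]), 0.0)
        rng = _FixedRng([1.0, 1.0, 0.5, 0.5])
        cand = exploit_toward_leader(leader, leader, Bounds.cube(-10, 10, 2), rng)
        np.testing.assert_allclose(cand.values, leader.values)

    def test_toward_leader_matches_scalar_oracle(self):
        agent = SolutionVector(np.array([2.0, -3.0]))
        leader = SolutionVector(np.array([1.0, 1.0]), 0.0)
        bounds = Bounds.cube(-10, 10, 2)
        cand = exploit_toward_leader(agent, leader, bounds, np.random.default_rng(9))
        oracle_rng = np.random.default_rng(9)
        r2 = oracle_rng.random(2)
        r3 = oracle_rng.random(2)
        expected = [
            r2j * (s + r3j * (lj - s))
            for s, lj, r2j, r3j in zip(agent.values, leader.values, r2, r3)
        ]
        np.testing.assert_allclose(cand.values, expected, atol=1e-12)

    def test_around_leader_k_collapses_at_t0(self):
        best = SolutionVector(np.array([1.0, 2.0]), 0.0)
        # z = 0, then h and a benign angle
        rng = _FixedRng([0.0, 0.5, 0.5])  # z, h/2, x/180
        cand = exploit_around_leader(best, 0, 10, Bounds.cube(-100, 100, 2), rng)
        r = ber_radius(1.0, 90.0)  # h = 2*0.5, x = 180*0.5
        np.testing.assert_allclose(cand.values, r * best.values, atol=1e-12)

    def test_around_leader_k_at_final_iteration(self):
        best = SolutionVector(np.array([0.0, 0.0]), 0.0)
        rng = _FixedRng([0.5, 0.5, 1.0 / 3.0])  # z=0.5 -> k = 0.5 + 2 = 2.5
        cand = exploit_around_leader(best, 10, 10, Bounds.cube(-100, 100, 2), rng)
        r = ber_radius(1.0, 60.0)
        np.testing.assert_allclose(cand.values, r * 2.5, atol=1e-12)

    def test_mutation_ignores_population_and_matches_oracle(self):
        bounds = Bounds.cube(-50, 50, 4)
        seed = 77
        cand = mutation_step(2, 10, bounds, np.random.default_rng(seed))
        oracle_rng = np.random.default_rng(seed)
        expected = []
        for _ in range(4):
            z = oracle_rng.random()
            h = 2.0 * oracle_rng.random()
            while True:
                x = 180.0 * oracle_rng.random()
                if x > 0 and abs(1.0 - math.cos(math.radians(x))) >= 1e-12:
                    break
            k = z + 2.0 * 2 * 2 / (10 * 10)
            expected.append(k * z * z - h * math.cos(math.radians(x)) / (1.0 - math.cos(math.radians(x))))
        np.testing.assert_allclose(cand.values, np.clip(expected, -50, 50), atol=1e-12)

    def test_candidates_respect_bounds(self):
        tight = Bounds.cube(-0.1, 0.1, 3)
        rng = np.random.default_rng(5)
        agent = SolutionVector(np.array([0.1, -0.1, 0.05]))
        for _ in range(50):
            for cand in (
                exploration_step(agent, tight, rng),
                mutation_step(3, 10, tight, rng),
                exploit_around_leader(agent, 3, 10, tight, rng),
            ):
                assert np.all(cand.values >= tight.lb - 1e-15)
                assert np.all(cand.values <= tight.ub + 1e-15)


def sphere(x):
    return float(np.sum(x * x))


class TestIterateAndOptimize:
    def test_full_iteration_matches_scalar_transcription(self):
        """One iteration on 3 agents, d=2, transcribed equation by equation."""
        bounds = Bounds.cube(-5.0, 5.0, 2)
        config = BERConfig(population_size=3, iterations=10, seed=123)
        state = init_state(sphere, bounds, config)
        ber_iterate(state, sphere)

        # oracle: replay the identical draw stream with scalar arithmetic
        rng = np.random.default_rng(123)
        agents = []
        for _ in range(3):
            r = rng.random(2)
            pos = [-5.0 + rj * 10.0 for rj in r]
            agents.append([pos, pos[0] ** 2 + pos[1] ** 2])
        best = min(agents, key=lambda a: a[1])
        best = [list(best[0]), best[1]]

        # agents 0 and 1 explore (n_explore = 2), agent 2 exploits
        for i in range(2):
            s, f = agents[i]
            r1 = rng.random(2)
            r2 = rng.random(2)
            cand = [
                min(max(s[j] + r1[j] * (s[j] - 1.0) * (2.0 * r2[j] - 1.0), -5.0), 5.0)
                for j in range(2)
            ]
            fc = cand[0] ** 2 + cand[1] ** 2
            if fc < f:
                agents[i] = [cand, fc]
            if agents[i][1] < best[1]:
                best = [list(agents[i][0]), agents[i][1]]
        coin = rng.random()
        s, f = agents[2]
        if coin < 0.5:
            r2 = rng.random(2)
            r3 = rng.random(2)
            cand = [
                min(max(r2[j] * (s[j] + r3[j] * (best[0][j] - s[j])), -5.0), 5.0)
                for j in range(2)
            ]
        else:
            z = rng.random()
            h = 2.0 * rng.random()
            while True:
                x = 180.0 * rng.random()
                if x > 0 and abs(1.0 - math.cos(math.radians(x))) >= 1e-12:
                    break
            r = h * math.cos(math.radians(x)) / (1.0 - math.cos(math.radians(x)))
            k = z + 2.0 * 1 * 1 / (10 * 10)
            cand = [min(max(r * (best[0][j] + k), -5.0), 5.0) for j in range(2)]
        fc = cand[0] ** 2 + cand[1] ** 2
        if fc < f:
            agents[2] = [cand, fc]
        if agents[2][1] < best[1]:
            best = [list(agents[2][0]), agents[2][1]]

        for impl, oracle in zip(state.agents, agents):
            np.testing.assert_allclose(impl.values, oracle[0], atol=1e-12)
            assert impl.fitness == pytest.approx(oracle[1], abs=1e-12)
        assert state.best_ever.fitness == pytest.approx(best[1], abs=1e-12)

    def test_elitism_history_non_increasing(self):
        bounds = Bounds.cube(-5, 5, 4)
        for seed in range(5):
            _, hist = ber_optimize(sphere, bounds, BERConfig(8, 30, seed=seed))
            assert len(hist) == 30
            assert all(a >= b for a, b in zip(hist, hist[1:]))

    def test_best_is_minimum_over_evaluations(self):
        seen = []

        def tracking(x):
            f = sphere(x)
            seen.append(f)
            return f

        best, _ = ber_optimize(tracking, Bounds.cube(-5, 5, 3), BERConfig(6, 20, seed=3))
        assert best.fitness == pytest.approx(min(seen))

    def test_same_seed_identical_history(self):
        bounds = Bounds.cube(-5, 5, 3)
        cfg = BERConfig(6, 25, seed=11)
        _, h1 = ber_optimize(sphere, bounds, cfg)
        _, h2 = ber_optimize(sphere, bounds, cfg)
        assert h1 == h2

    def test_non_finite_fitness_recorded_as_inf(self):
        def bad(x):
            return float("nan")

        with pytest.warns(UserWarning):
            best, _ = ber_optimize(bad, Bounds.cube(-1, 1, 2), BERConfig(4, 2, seed=0))
        assert math.isinf(best.fitness)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            ber_optimize(sphere, Bounds(np.empty(0), np.empty(0)), BERConfig(4, 2))


class TestStagnationMutation:
    def test_mutation_fires_exactly_at_window(self):
        """Constant fitness: mutation at iteration 3, never earlier."""
        const = lambda x: 1.0  # noqa: E731
        cfg = BERConfig(6, 10, seed=0, stagnation_window=3)
        state = init_state(const, Bounds.cube(-1, 1, 2), cfg)
        fired_at = []
        for it in range(1, 7):
            ber_iterate(state, const)
            if state.mutation_fired:
                fired_at.append(it)
        assert fired_at == [3, 6]

    def test_no_mutation_while_improving(self):
        # fitness keeps improving: stagnation never accumulates
        calls = {"n": 0}

        def improving(x):
            calls["n"] += 1
            return 1000.0 / calls["n"]

        cfg = BERConfig(4, 10, seed=1, stagnation_window=3)
        state = init_state(improving, Bounds.cube(-1, 1, 2), cfg)
        for _ in range(10):
            ber_iterate(state, improving)
            assert not state.mutation_fired

    def test_counter_resets_after_firing(self):
        const = lambda x: 1.0  # noqa: E731
        cfg = BERConfig(6, 20, seed=0)
        state = init_state(const, Bounds.cube(-1, 1, 2), cfg)
        for _ in range(3):
            ber_iterate(state, const)
        assert state.mutation_fired and state.stagnation_counter == 0


def test_run_log_csv_schema(tmp_path):
    from histotune.optimizers import write_run_log

    log = []
    ber_optimize(sphere, Bounds.cube(-5, 5, 3), BERConfig(6, 5, seed=0), log=log)
    assert len(log) == 5
    path = tmp_path / "run.csv"
    write_run_log(path, log)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "iteration,best_fitness,mean_fitness,mutation_fired"
    assert len(lines) == 6
    first = lines[1].split(",")
    assert first[0] == "1" and first[3] in ("0", "1")


class TestSphereConvergence:
    def test_reduces_sphere_by_two_orders(self):
        """d=5, pop 20, 200 iterations: <=1% of the initial best, >=18/20 seeds."""
        bounds = Bounds.cube(-5.0, 5.0, 5)
        hits = 0
        for seed in range(20):
            cfg = BERConfig(20, 200, seed=seed)
            f0 = init_state(sphere, bounds, cfg).best_ever.fitness
            best, hist = ber_optimize(sphere, bounds, cfg)
            assert all(a >= b for a, b in zip(hist, hist[1:]))
            if best.fitness <= 0.01 * f0:
                hits += 1
        assert hits >= 18
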