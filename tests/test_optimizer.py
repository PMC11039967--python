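"""CMA-ES on standard benchmarks, determinism, restarts and warm starts."""

import numpy as np
import pytest

from sit2walk.controller import ParamVector
from sit2walk.optimizer import (OptimizationConfig, optimize, optimize_parallel,
                                warm_start_chain)


def vec(n, init=2.0, lo=-5.0, hi=5.0):
    return ParamVector([f"x{i}" for i in range(n)], np.full(n, init),
                       np.full(n, lo), np.full(n, hi), np.full(n, 0.3))


def sphere(pv):
    return float(np.sum(pv.values ** 2))


def ellipsoid(pv):
    n = len(pv)
    w = 10.0 ** (2 * np.arange(n) / max(n - 1, 1))
    return float(np.sum(w * pv.values ** 2))


class TestCMAES:
    def test_sphere_10d_to_1e8(self):
        cfg = OptimizationConfig(population_size=10, max_generations=300,
                                 sigma0=0.3, seed=5)
        res = optimize(sphere, vec(10), cfg)
        assert res.best_cost < 1e-8
        assert res.generations <= 300

    def test_convex_quadratic_converges(self):
        cfg = OptimizationConfig(population_size=12, max_generations=400,
                                 sigma0=0.3, seed=2, stagnation_gens=400)
        res = optimize(ellipsoid, vec(6), cfg)
        assert res.best_cost < 1e-6

    def test_identical_seed_identical_trace(self):
        cfg = OptimizationConfig(population_size=10, max_generations=40,
                                 sigma0=0.3, seed=11)
        r1 = optimize(sphere, vec(8), cfg)
        r2 = optimize(sphere, vec(8), cfg)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.best_params.values, r2.best_params.values)

    def test_zero_budget_returns_start(self):
        cfg = OptimizationConfig(max_generations=0, seed=0)
        res = optimize(sphere, vec(4), cfg)
        np.testing.assert_allclose(res.best_params.values, 2.0)
        assert res.best_cost == pytest.approx(16.0)

    def test_best_never_regresses(self):
        cfg = OptimizationConfig(population_size=10, max_generations=60,
                                 sigma0=0.3, seed=3)
        res = optimize(sphere, vec(6), cfg)
        best_ever = res.trace[:, 2]
        assert np.all(np.diff(best_ever) <= 0)

    def test_bounds_respected(self):
        seen = []

        def bounded(pv):
            seen.append(pv.values.copy())
            return sphere(pv)

        cfg = OptimizationConfig(population_size=8, max_generations=20,
                                 sigma0=0.5, seed=7)
        optimize(bounded, vec(5), cfg)
        allv = np.array(seen)
        assert allv.min() >= -5.0 - 1e-12 and allv.max() <= 5.0 + 1e-12

    def test_fixed_entries_not_optimized(self):
        x0 = vec(6)
        x0.free[2] = False

        def cost(pv):
            assert pv.values[2] == 2.0
            return sphere(pv)

        res = optimize(cost, x0, OptimizationConfig(population_size=8,
                                                    max_generations=30, seed=1))
        assert res.best_params.values[2] == 2.0


class TestRestartsAndChains:
    def test_parallel_restart_selects_minimum(self):
        cfg = OptimizationConfig(population_size=8, max_generations=25,
                                 sigma0=0.3, seed=4, n_parallel=3)
        res = optimize_parallel(sphere, vec(5), cfg)
        assert res.best_cost == min(res.meta["restart_costs"])

    def test_chain_warm_starts_each_condition(self):
        targets = {"a": 1.0, "b": 2.0, "c": 3.0}
        calls = {}

        def factory(cond):
            def cost(pv):
                calls.setdefault(cond, []).append(pv.values.copy())
                return float(np.sum((pv.values - targets[cond]) ** 2))
            return cost

        cfg = OptimizationConfig(population_size=8, max_generations=40,
                                 sigma0=0.2, seed=6, n_parallel=1)
        results = warm_start_chain(["a", "b", "c"], vec(4, init=0.0), factory, cfg)
        # each condition converges near its own target
        for res, tgt in zip(results, (1.0, 2.0, 3.0)):
            assert res.best_cost < 1e-2
        # condition b's first evaluation starts from condition a's solution
        first_b = calls["b"][0]
        np.testing.assert_allclose(first_b, results[0].best_params.values)

    def test_chain_of_length_one_equals_optimize(self):
        cfg = OptimizationConfig(population_size=8, max_generations=30,
                                 sigma0=0.3, seed=9, n_parallel=1)
        chain = warm_start_chain(["only"], vec(4), lambda c: sphere, cfg)
        single_cfg = OptimizationConfig(**{**cfg.__dict__, "seed": cfg.seed})
        single = optimize_parallel(sphere, vec(4), single_cfg)
        assert chain[0].best_cost == pytest.approx(single.best_cost)

    def test_infeasible_condition_flagged_and_skipped(self):
        def factory(cond):
            return sphere

        def feasibility(cond, params):
            return cond != "bad"

        cfg = OptimizationConfig(population_size=8, max_generations=10,
                                 sigma0=0.2, seed=8, n_parallel=1)
        results = warm_start_chain(["ok", "bad", "after"], vec(3), factory, cfg,
                                   feasibility_fn=feasibility)
        assert [r.no_solution for r in results] == [False, True, False]
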