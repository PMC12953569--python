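"""Optimizer unit and property tests: chaos, spiral, mutation, elitism, bounds."""

import numpy as np
import pytest
from scipy import stats

from ieto_automl.optimize import (
    ALGORITHMS,
    Bounds,
    OptimizerSettings,
    binarize,
    cauchy_mutation,
    exploration_probability,
    logistic_chaotic_init,
    logistic_map_step,
    run_optimizer,
    spiral_step,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestBounds:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            Bounds(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_clip_and_contains(self):
        b = Bounds.cube(-1.0, 1.0, 3)
        assert b.contains(b.clip(np.array([5.0, -5.0, 0.0])))


class TestChaoticInit:
    def test_map_step_closed_form(self):
        assert logistic_map_step(0.3) == pytest.approx(0.84)

    def test_positions_within_bounds_and_deterministic(self):
        b = Bounds(np.array([-2.0, 0.0]), np.array([3.0, 10.0]))
        a1 = logistic_chaotic_init(50, b, seed=9)
        a2 = logistic_chaotic_init(50, b, seed=9)
        assert a1.shape == (50, 2)
        assert np.array_equal(a1, a2)
        assert np.all(a1 >= b.lower) and np.all(a1 <= b.upper)

    def test_iterates_follow_arcsine_invariant_density(self):
        """10^4 iterates of the r=4 map match the Beta(1/2,1/2) CDF (KS, 1% level)."""
        x, xs = 0.3123, []
        for _ in range(10_000):
            x = logistic_map_step(x)
            xs.append(x)
        ks = stats.kstest(xs, stats.beta(0.5, 0.5).cdf)
        assert ks.statistic < 1.63 / np.sqrt(len(xs))  # 1% critical value


class TestSpiralStep:
    def test_identity_at_best(self, rng):
        b = Bounds.cube(-5.0, 5.0, 4)
        best = np.array([1.0, -1.0, 0.0, 2.0])
        out = spiral_step(best.copy(), best, rng, b)
        assert np.allclose(out, best)

    def test_stays_in_bounds(self, rng):
        b = Bounds.cube(-1.0, 1.0, 3)
        for _ in range(200):
            out = spiral_step(rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3), rng, b)
            assert b.contains(out)

    def test_step_radii_match_exponential_cosine_law(self, rng):
        """Scaled step radii reproduce the e^{bl} cos(2 pi l) magnitude law."""
        b = Bounds.cube(-1e9, 1e9, 1)  # wide box: no clipping
        current, best = np.array([0.0]), np.array([1.0])
        draws = np.array(
            [abs(spiral_step(current, best, rng, b)[0] - best[0]) for _ in range(10_000)]
        )
        oracle_rng = np.random.default_rng(777)  # independent route: direct formula
        l = oracle_rng.uniform(-1.0, 1.0, 10_000)
        oracle = np.abs(np.exp(l) * np.cos(2 * np.pi * l))
        assert stats.ks_2samp(draws, oracle).pvalue > 0.01


class TestCauchyMutation:
    def test_zero_scale_identity(self, rng):
        b = Bounds.cube(-5.0, 5.0, 3)
        x = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(cauchy_mutation(x, 0.0, rng, b), x)

    def test_clipped_to_bounds(self, rng):
        b = Bounds.cube(-1.0, 1.0, 5)
        for _ in range(100):
            assert b.contains(cauchy_mutation(np.zeros(5), 10.0, rng, b))

    def test_median_absolute_perturbation_equals_scale(self, rng):
        """|scale * C| has median = scale (|Cauchy| median is 1 at unit scale)."""
        b = Bounds.cube(-1e12, 1e12, 1)
        scale = 0.37
        moves = np.array(
            [cauchy_mutation(np.zeros(1), scale, rng, b)[0] for _ in range(100_000)]
        )
        assert np.median(np.abs(moves)) == pytest.approx(scale, rel=0.05)


class TestExplorationSchedule:
    @pytest.mark.parametrize("it,expected", [(0, 1.0), (100, 0.0), (50, 0.5)])
    def test_linear_schedule(self, it, expected):
        assert exploration_probability(it, 100) == pytest.approx(expected)

    def test_monotone_non_increasing(self):
        vals = [exploration_probability(t, 250) for t in range(251)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestBinarize:
    def test_bits_binary_and_length(self, rng):
        bits = binarize(np.linspace(-3, 3, 17), rng)
        assert bits.shape == (17,)
        assert set(np.unique(bits)) <= {0, 1}

    def test_extreme_positions_saturate(self, rng):
        assert binarize(np.full(100, 50.0), rng).all()
        assert not binarize(np.full(100, -50.0), rng).any()

    def test_zero_position_is_fair_coin(self, rng):
        freq = np.mean([binarize(np.zeros(1), rng)[0] for _ in range(10_000)])
        assert freq == pytest.approx(0.5, abs=0.02)


class TestRunOptimizer:
    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_constant_objective_flat_trajectory(self, alg):
        b = Bounds.cube(-1.0, 1.0, 3)
        s = OptimizerSettings(algorithm=alg, population_size=5, max_iterations=20, seed=0)
        opt = run_optimizer(lambda x: 0.0, b, s)
        assert opt.fitness == 0.0
        assert np.all(opt.trajectory.best_fitness == 0.0)

    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_elitism_bounds_and_determinism(self, alg):
        b = Bounds.cube(-10.0, 10.0, 5)
        visited = []

        def instrumented(x):
            visited.append(np.array(x))
            return sphere(x)

        s = OptimizerSettings(algorithm=alg, population_size=8, max_iterations=40, seed=5)
        opt = run_optimizer(instrumented, b, s)
        # elitism: monotone best-fitness trajectory
        assert np.all(np.diff(opt.trajectory.best_fitness) <= 0)
        # bound preservation on every visited position
        stack = np.vstack(visited)
        assert np.all(stack >= b.lower - 1e-12) and np.all(stack <= b.upper + 1e-12)
        # optimum consistency
        assert opt.fitness == pytest.approx(sphere(opt.position))
        assert opt.fitness == opt.trajectory.best_fitness.min()
        # bit-identical rerun
        opt2 = run_optimizer(sphere, b, s)
        assert np.array_equal(opt.position, opt2.position)
        assert opt.fitness == opt2.fitness

    def test_ieto_solves_sphere_and_beats_random_search(self):
        b = Bounds.cube(-100.0, 100.0, 10)
        s = OptimizerSettings(algorithm="ieto", population_size=30,
                              max_iterations=200, seed=1)
        opt = run_optimizer(sphere, b, s)
        assert opt.fitness < 1e-3
        # random-search oracle with the same evaluation budget
        rng = np.random.default_rng(1)
        X = rng.uniform(-100, 100, size=(opt.evaluations, 10))
        random_best = np.min(np.sum(X**2, axis=1))
        assert opt.fitness < random_best / 1e3

    def test_ieto_median_not_worse_than_eto_on_sphere(self):
        b = Bounds.cube(-100.0, 100.0, 10)
        finals = {"ieto": [], "eto": []}
        for alg in finals:
            for seed in range(1, 11):
                s = OptimizerSettings(algorithm=alg, population_size=15,
                                      max_iterations=100, seed=seed)
                finals[alg].append(run_optimizer(sphere, b, s).fitness)
        assert np.median(finals["ieto"]) <= np.median(finals["eto"])

    def test_non_finite_objective_never_propagates(self):
        b = Bounds.cube(-5.0, 5.0, 2)

        def spiky(x):
            if x[0] > 0:
                return np.nan
            return sphere(x)

        s = OptimizerSettings(algorithm="ieto", population_size=6, max_iterations=30, seed=2)
        opt = run_optimizer(spiky, b, s)
        assert np.isfinite(opt.fitness)
        assert np.all(np.isfinite(opt.trajectory.best_fitness))
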