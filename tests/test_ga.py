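import itertools

import numpy as np
import pytest

from chromaroi.errors import DomainError
from chromaroi.ga import (
    Chromosome,
    FitnessEvaluator,
    GAConfig,
    crossover_single_point,
    evolve,
    init_population,
    monte_carlo_reliability,
    mutate,
    repair,
    roulette_select,
    run_restarts,
)
from chromaroi.histograms import build_feature_matrix
from chromaroi.image_grid import partition_image
from chromaroi.pls import loocv_curve, pick_lv


@pytest.fixture(scope="module")
def small_evaluator(small_set):
    return FitnessEvaluator(
        small_set.samples(), small_set.spec.grid(), ("R", "G", "B"), lv_max=4
    )


class TestInitPopulation:
    def test_nim_one_gives_single_gene(self, rng):
        grid = partition_image((40, 40), 4, 4)
        cfg = GAConfig(population_size=20, nim=1)
        pop = init_population(cfg, grid, rng)
        assert all(c.n_selected == 1 for c in pop)

    def test_same_seed_identical_population(self):
        grid = partition_image((40, 40), 4, 4)
        cfg = GAConfig(population_size=15, nim=8)
        pops = [
            init_population(cfg, grid, np.random.default_rng(42)) for _ in range(2)
        ]
        for a, b in zip(*pops):
            np.testing.assert_array_equal(a.genes, b.genes)

    def test_ones_counts_span_range(self, rng):
        grid = partition_image((60, 60), 4, 4)
        cfg = GAConfig(population_size=10_000, nim=16)
        counts = {c.n_selected for c in init_population(cfg, grid, rng)}
        assert counts == set(range(1, 17))

    def test_nim_exceeding_grid(self, rng):
        grid = partition_image((40, 40), 2, 2)
        with pytest.raises(DomainError):
            init_population(GAConfig(nim=5), grid, rng)


class TestRoulette:
    def test_equal_fitness_uniform(self, rng):
        pop = [Chromosome(np.eye(4, dtype=bool)[i], fitness=2.0) for i in range(4)]
        draws = np.zeros(4)
        for _ in range(4000):
            a, b = roulette_select(pop, rng)
            draws[int(np.argmax(a.genes))] += 1
            draws[int(np.argmax(b.genes))] += 1
        freq = draws / draws.sum()
        assert np.all(np.abs(freq - 0.25) < 0.03)

    def test_half_rmsecv_doubles_frequency(self, rng):
        pop = [Chromosome(np.eye(4, dtype=bool)[i], fitness=2.0) for i in range(3)]
        pop.append(Chromosome(np.eye(4, dtype=bool)[3], fitness=1.0))
        hits = 0
        n = 50_000
        for _ in range(n):
            a, _ = roulette_select(pop, rng)
            hits += bool(a.genes[3])
        # weight 1.0 vs three of 0.5 -> expected share 0.4
        assert abs(hits / n - 0.4) < 0.02

    def test_only_finite_member_always_selected(self, rng):
        pop = [
            Chromosome(np.array([True, False]), fitness=float("inf")),
            Chromosome(np.array([False, True]), fitness=3.0),
        ]
        for _ in range(50):
            a, b = roulette_select(pop, rng)
            assert a.genes[1] and b.genes[1]


class TestOperators:
    def test_identical_parents_identical_offspring(self, rng):
        genes = np.array([True, False, True, True])
        a, b = crossover_single_point(Chromosome(genes), Chromosome(genes), rng)
        np.testing.assert_array_equal(a.genes, genes)
        np.testing.assert_array_equal(b.genes, genes)

    def test_cut_at_one(self):
        # a 3-gene chromosome has cuts in {1, 2}; force cut 1 via a rigged rng
        class Rig:
            def integers(self, lo, hi=None):
                return 1
        a, b = crossover_single_point(
            Chromosome(np.array([1, 0, 0], bool)),
            Chromosome(np.array([0, 1, 1], bool)),
            Rig(),
        )
        np.testing.assert_array_equal(a.genes, [1, 1, 1])
        np.testing.assert_array_equal(b.genes, [0, 0, 0])

    def test_positionwise_gene_conservation(self, rng):
        for _ in range(20):
            ga = rng.random(10) < 0.5
            gb = rng.random(10) < 0.5
            a, b = crossover_single_point(Chromosome(ga), Chromosome(gb), rng)
            np.testing.assert_array_equal(
                np.sort(np.c_[a.genes, b.genes], axis=1),
                np.sort(np.c_[ga, gb], axis=1),
            )

    def test_mutation_rate_zero_identity(self, rng):
        genes = rng.random(20) < 0.5
        out = mutate(Chromosome(genes), 0.0, rng)
        np.testing.assert_array_equal(out.genes, genes)

    def test_mutation_rate_one_complement(self, rng):
        genes = rng.random(20) < 0.5
        out = mutate(Chromosome(genes), 1.0, rng)
        np.testing.assert_array_equal(out.genes, ~genes)

    def test_mutation_flip_expectation(self, rng):
        genes = np.zeros(100, dtype=bool)
        flips = [
            mutate(Chromosome(genes), 0.05, rng).n_selected for _ in range(2000)
        ]
        assert np.mean(flips) == pytest.approx(5.0, abs=0.3)

    def test_repair_all_zero(self, rng):
        out = repair(Chromosome(np.zeros(4, dtype=bool)), 2, rng)
        assert out.n_selected == 1

    def test_repair_within_bound_unchanged(self, rng):
        genes = np.array([True, True, False, False])
        out = repair(Chromosome(genes), 2, rng)
        np.testing.assert_array_equal(out.genes, genes)

    def test_repair_trims_to_nim_subset(self, rng):
        genes = np.ones(8, dtype=bool)
        out = repair(Chromosome(genes), 5, rng)
        assert out.n_selected == 5
        assert np.all(genes[out.genes])  # survivors were previously set


class TestFitness:
    def test_all_ones_equals_full_image_model(self, small_set, small_evaluator):
        grid = small_set.spec.grid()
        rmsecv, n_lv = small_evaluator.evaluate(np.ones(grid.n, dtype=bool))
        fm = build_feature_matrix(
            small_set.samples(), grid, range(1, grid.n + 1), ("R", "G", "B")
        )
        X = fm.X[:, np.ptp(fm.X, axis=0) > 0]
        curve, _ = loocv_curve(X, fm.y, min(4, X.shape[1]))
        expected_lv = pick_lv(curve)
        assert n_lv == expected_lv
        assert rmsecv == pytest.approx(curve[expected_lv - 1])

    def test_cache_correctness(self, small_set):
        ev = FitnessEvaluator(
            small_set.samples(), small_set.spec.grid(), ("R",), lv_max=3
        )
        g = np.zeros(ev.grid.n, dtype=bool)
        g[[2, 5]] = True
        f1 = ev.evaluate(g)
        evals = ev.n_evaluations
        f2 = ev.evaluate(g.copy())
        assert f1 == f2 and ev.n_evaluations == evals and ev.n_cache_hits == 1

    def test_matches_exhaustive_subset_models(self, tiny_set):
        """Evaluator fitness equals a from-scratch histogram+LOOCV build for
        every one of the 15 valid subsets of a 2x2 grid."""
        grid = tiny_set.spec.grid()
        ev = FitnessEvaluator(tiny_set.samples(), grid, ("R", "G", "B"), lv_max=3)
        for k in (1, 2, 3, 4):
            for combo in itertools.combinations(range(1, 5), k):
                genes = np.zeros(4, dtype=bool)
                genes[[c - 1 for c in combo]] = True
                fit, _ = ev.evaluate(genes)
                fm = build_feature_matrix(
                    tiny_set.samples(), grid, combo, ("R", "G", "B")
                )
                X = fm.X[:, np.ptp(fm.X, axis=0) > 0]
                curve, _ = loocv_curve(X, fm.y, min(3, X.shape[1]))
                assert fit == pytest.approx(curve[pick_lv(curve) - 1])


class TestEvolve:
    def test_best_per_generation_non_increasing(self, small_evaluator):
        cfg = GAConfig(population_size=12, generations=8, nim=3, seed=5)
        res = evolve(cfg, small_evaluator, np.random.default_rng(5))
        curve = np.array(res.best_per_generation)
        assert len(curve) == 8
        assert np.all(np.diff(curve) <= 1e-12)

    def test_single_generation_runs(self, small_evaluator):
        cfg = GAConfig(population_size=8, generations=1, nim=2, seed=1)
        res = evolve(cfg, small_evaluator, np.random.default_rng(1))
        assert len(res.best_per_generation) == 1
        assert np.isfinite(res.best_rmsecv)

    def test_reproducible_from_seed(self, small_evaluator):
        cfg = GAConfig(population_size=10, generations=4, nim=3, seed=9)
        a = evolve(cfg, small_evaluator, np.random.default_rng(9))
        b = evolve(cfg, small_evaluator, np.random.default_rng(9))
        np.testing.assert_array_equal(a.best.genes, b.best.genes)
        assert a.best_per_generation == b.best_per_generation

    def test_every_chromosome_respects_nim(self, small_set):
        class Spy(FitnessEvaluator):
            seen = []
            def evaluate(self, genes):
                self.seen.append(int(np.asarray(genes, bool).sum()))
                return super().evaluate(genes)
        ev = Spy(small_set.samples(), small_set.spec.grid(), ("R",), lv_max=2)
        cfg = GAConfig(population_size=10, generations=3, nim=2, seed=0)
        evolve(cfg, ev, np.random.default_rng(0))
        assert all(1 <= k <= 2 for k in ev.seen)


class TestRestartsAndReliability:
    def test_single_restart_equals_evolve(self, small_evaluator):
        cfg = GAConfig(population_size=10, generations=3, nim=3, n_restarts=1, seed=2)
        best, runs = run_restarts(cfg, small_evaluator)
        assert len(runs) == 1 and best is runs[0]

    def test_best_of_restarts_is_min(self, small_evaluator):
        cfg = GAConfig(population_size=8, generations=3, nim=3, n_restarts=4, seed=3)
        best, runs = run_restarts(cfg, small_evaluator)
        assert best.best_rmsecv == min(r.best_rmsecv for r in runs)
        assert all(best.best_rmsecv <= r.best_rmsecv for r in runs)

    def test_restarts_reproducible_from_master_seed(self, small_evaluator):
        cfg = GAConfig(population_size=8, generations=3, nim=3, n_restarts=3, seed=4)
        b1, _ = run_restarts(cfg, small_evaluator)
        b2, _ = run_restarts(cfg, small_evaluator)
        np.testing.assert_array_equal(b1.best.genes, b2.best.genes)

    def test_planted_cell_recovered_across_seeds(self, small_set):
        """On a 3x3 grid with one planted cell, the best chromosome includes
        the planted cell in at least 9 of 10 seeded best-of-1 runs."""
        grid = small_set.spec.grid()
        ev = FitnessEvaluator(small_set.samples(), grid, ("R", "G", "B"), lv_max=4)
        truth = next(iter(small_set.truth_indices()))
        hits = 0
        for seed in range(10):
            cfg = GAConfig(
                population_size=16, generations=8, nim=2, n_restarts=1, seed=seed
            )
            best, _ = run_restarts(cfg, ev)
            hits += truth in best.best.selected_indices()
        assert hits >= 9

    def test_monte_carlo_frequencies(self, small_set):
        grid = small_set.spec.grid()
        ev = FitnessEvaluator(small_set.samples(), grid, ("R", "G", "B"), lv_max=4)
        cfg = GAConfig(population_size=12, generations=6, nim=2, seed=0)
        freqs = monte_carlo_reliability(cfg, ev, n_mc=5)
        assert freqs.shape == (grid.n,)
        assert np.all((freqs >= 0) & (freqs <= 1))
        truth = next(iter(small_set.truth_indices()))
        assert freqs[truth - 1] == freqs.max()

    def test_n_mc_lower_bound(self, small_evaluator):
        with pytest.raises(DomainError):
            monte_carlo_reliability(GAConfig(seed=0), small_evaluator, n_mc=1)
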