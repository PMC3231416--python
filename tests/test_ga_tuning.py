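import numpy as np
import pytest

import residuecov as rc
from residuecov.ga_tuning import (
    GENE_LOWER,
    GENE_UPPER,
    GAConfig,
    Individual,
    _Evaluator,
    fitness,
    gaussian_mutate,
    initialize_population,
    mean_fitness,
    mutation_sigma,
    roulette_select,
    two_point_crossover,
)


class TestFitness:
    def test_identical_masks_score_zero(self, rng):
        mask = rng.integers(0, 2, size=(32, 32)).astype(np.uint8)
        assert fitness(mask, mask) == 0.0

    def test_complement_scores_one(self, rng):
        mask = rng.integers(0, 2, size=(32, 32)).astype(np.uint8)
        assert fitness(mask, 1 - mask) == 1.0

    def test_single_pixel_difference(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = a.copy()
        b[1, 2] = 1
        assert fitness(a, b) == pytest.approx(1 / 16)

    def test_symmetric(self, rng):
        a = rng.integers(0, 2, size=(16, 16)).astype(np.uint8)
        b = rng.integers(0, 2, size=(16, 16)).astype(np.uint8)
        assert fitness(a, b) == fitness(b, a)

    def test_triangle_inequality(self, rng):
        """Normalized Hamming distance is a metric."""
        for _ in range(50):
            a, b, c = (rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
                       for _ in range(3))
            assert fitness(a, c) <= fitness(a, b) + fitness(b, c) + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fitness(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMeanFitness:
    def test_single_pair_equals_fitness(self, consistent_pair, known_params):
        img, template = consistent_pair
        seg = rc.segment(img, known_params)
        assert mean_fitness(known_params, [(img, template)]) == fitness(seg, template)

    def test_arithmetic_mean_over_pairs(self, consistent_pair, known_params):
        img, template = consistent_pair
        f_good = mean_fitness(known_params, [(img, template)])
        f_bad = mean_fitness(known_params, [(img, 1 - template)])
        both = mean_fitness(known_params, [(img, template), (img, 1 - template)])
        assert both == pytest.approx((f_good + f_bad) / 2)

    def test_consistent_pair_scores_zero(self, consistent_pair, known_params):
        assert mean_fitness(known_params, [consistent_pair]) == 0.0

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            mean_fitness(rc.TABLE1, [])

    def test_fast_evaluator_matches_reference(self, consistent_pair, rng):
        """The GA's precomputed evaluator is arithmetically identical to
        running the full segmentation per candidate."""
        evaluator = _Evaluator([consistent_pair], rc.DEFAULT_VEGETATION)
        for _ in range(10):
            genes = rng.uniform(GENE_LOWER, GENE_UPPER)
            params = rc.SegmentationParams(*genes)
            assert evaluator(genes) == mean_fitness(params, [consistent_pair])


class TestPopulation:
    def test_size_and_bounds(self):
        pop = initialize_population(GAConfig(seed=0))
        assert len(pop) == 100
        for ind in pop:
            assert (ind.genes >= GENE_LOWER).all() and (ind.genes <= GENE_UPPER).all()

    def test_same_seed_identical(self):
        a = initialize_population(GAConfig(seed=5))
        b = initialize_population(GAConfig(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.genes, y.genes)

    def test_uniform_coverage_of_bounds(self):
        genes = np.array([i.genes for i in initialize_population(
            GAConfig(population_size=10_000, seed=1))])
        assert genes.min(axis=0) == pytest.approx(GENE_LOWER, abs=0.3 * 25.5)
        assert genes.max(axis=0) == pytest.approx(GENE_UPPER, abs=0.3 * 25.5)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(crossover_prob=1.5)
        with pytest.raises(ValueError):
            GAConfig(elite_count=100, population_size=100)


class TestRoulette:
    def _pop(self, fitnesses):
        return [Individual(np.zeros(4) + i, f) for i, f in enumerate(fitnesses)]

    def test_unique_perfect_individual_always_wins(self, rng):
        pop = self._pop([0.0, 1.0, 1.0])
        for _ in range(100):
            assert roulette_select(pop, rng).fitness == 0.0

    def test_uniform_when_all_equal(self, rng):
        pop = self._pop([0.5] * 4)
        draws = np.array([roulette_select(pop, rng).genes[0] for _ in range(10_000)])
        counts = np.bincount(draws.astype(int), minlength=4)
        # multinomial: sd of each count ~ sqrt(n p (1-p)) ~ 43
        assert np.abs(counts - 2500).max() < 3 * 43.3

    def test_two_to_one_goodness_ratio(self, rng):
        pop = self._pop([0.2, 0.6])  # goodness 0.8 vs 0.4
        draws = np.array([roulette_select(pop, rng).genes[0] for _ in range(10_000)])
        frac = (draws == 0).mean()
        assert frac == pytest.approx(2 / 3, abs=3 * 0.0047)

    def test_all_zero_goodness_falls_back_to_uniform(self, rng):
        pop = self._pop([1.0, 1.0])
        draws = {roulette_select(pop, rng).genes[0] for _ in range(200)}
        assert draws == {0.0, 1.0}

    def test_unevaluated_population_rejected(self, rng):
        with pytest.raises(RuntimeError):
            roulette_select([Individual(np.zeros(4))], rng)


class TestCrossover:
    def test_prob_zero_copies_parents(self, rng):
        p1 = Individual(np.array([1.0, 2.0, 3.0, 4.0]))
        p2 = Individual(np.array([5.0, 6.0, 7.0, 8.0]))
        c1, c2 = two_point_crossover(p1, p2, rng, prob=0.0)
        np.testing.assert_array_equal(c1.genes, p1.genes)
        np.testing.assert_array_equal(c2.genes, p2.genes)

    def test_middle_segment_swapped(self, rng):
        """With prob=1 offspring keep their parent's ends and exchange a
        contiguous middle segment cut at gene boundaries."""
        p1 = Individual(np.array([1.0, 2.0, 3.0, 4.0]))
        p2 = Individual(np.array([5.0, 6.0, 7.0, 8.0]))
        for _ in range(50):
            c1, c2 = two_point_crossover(p1, p2, rng, prob=1.0)
            swapped = c1.genes != p1.genes
            assert (c1.genes[swapped] == p2.genes[swapped]).all()
            assert (c2.genes[swapped] == p1.genes[swapped]).all()
            assert (c2.genes[~swapped] == p2.genes[~swapped]).all()
            # cut points exclude the chromosome ends, so ends never swap
            assert not swapped[0] and not swapped[3]
            assert swapped.any()
            idx = np.flatnonzero(swapped)
            assert (np.diff(idx) == 1).all()  # contiguous segment

    def test_gene_multiset_conserved(self, rng):
        p1 = Individual(rng.uniform(-10, 10, 4))
        p2 = Individual(rng.uniform(-10, 10, 4))
        c1, c2 = two_point_crossover(p1, p2, rng, prob=1.0)
        np.testing.assert_allclose(
            np.sort(np.concatenate([c1.genes, c2.genes])),
            np.sort(np.concatenate([p1.genes, p2.genes])))


class TestMutation:
    def test_scale_zero_is_identity(self, rng):
        ind = Individual(np.array([1.0, -2.0, 3.0, 100.0]))
        out = gaussian_mutate(ind, 0, GAConfig(mutation_scale=0.0), rng)
        np.testing.assert_array_equal(out.genes, ind.genes)

    def test_schedule_endpoint_sigma_zero(self, rng):
        config = GAConfig(mutation_shrink=1.0, max_generations=100)
        assert (mutation_sigma(100, config) == 0.0).all()
        ind = Individual(np.array([1.0, -2.0, 3.0, 100.0]))
        out = gaussian_mutate(ind, 100, config, rng)
        np.testing.assert_array_equal(out.genes, ind.genes)

    def test_initial_sigma_matches_scale_times_range(self, rng):
        """Monte-Carlo: empirical spread of first-generation mutations."""
        config = GAConfig(mutation_scale=0.1, mutation_shrink=0.5)
        ind = Individual(np.array([0.0, 0.0, 0.0, 127.0]))
        deltas = np.array([
            gaussian_mutate(ind, 0, config, rng).genes - ind.genes
            for _ in range(10_000)])
        # coefficient range 20 -> sigma 2; sd of sample sd ~ sigma/sqrt(2n)
        assert deltas[:, 0].std() == pytest.approx(2.0, abs=3 * 2.0 / np.sqrt(2e4))

    def test_genes_clamped_to_bounds(self, rng):
        config = GAConfig(mutation_scale=5.0)  # huge noise
        ind = Individual(np.array([9.9, -9.9, 0.0, 250.0]))
        for _ in range(100):
            out = gaussian_mutate(ind, 0, config, rng)
            assert (out.genes >= GENE_LOWER).all() and (out.genes <= GENE_UPPER).all()

    def test_integer_threshold_mode(self, rng):
        config = GAConfig(integer_threshold=True)
        out = gaussian_mutate(Individual(np.array([0.0, 0.0, 0.0, 127.3])), 0, config, rng)
        assert out.genes[3] == round(out.genes[3])


class TestEvolve:
    def test_consistent_pair_reaches_fitness_stop(self, consistent_pair):
        result = rc.evolve([consistent_pair], config=GAConfig(seed=1))
        assert result.best.fitness <= 0.05
        assert result.stop_reason == "fitness_stop"

    def test_zero_generations_returns_initial_best(self, consistent_pair):
        config = GAConfig(seed=3, max_generations=0, fitness_stop=None)
        result = rc.evolve([consistent_pair], config=config)
        assert result.generations_run == 0
        assert result.stop_reason == "max_generations"
        pop = initialize_population(GAConfig(seed=3))
        evaluator = _Evaluator([consistent_pair], rc.DEFAULT_VEGETATION)
        assert result.best.fitness == min(evaluator(i.genes) for i in pop)

    def test_best_history_non_increasing(self, consistent_pair):
        result = rc.evolve([consistent_pair], config=GAConfig(seed=2))
        best = [b for _, b, _ in result.history]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))

    def test_reproducible_given_seed(self, consistent_pair):
        config = GAConfig(seed=11, max_generations=30, fitness_stop=None,
                          stall_generations=10)
        r1 = rc.evolve([consistent_pair], config=config)
        r2 = rc.evolve([consistent_pair], config=config)
        np.testing.assert_array_equal(r1.best.genes, r2.best.genes)
        assert r1.history == r2.history
        assert r1.stop_reason == r2.stop_reason

    def test_best_genes_within_bounds(self, consistent_pair):
        result = rc.evolve([consistent_pair], config=GAConfig(seed=4))
        assert (result.best.genes >= GENE_LOWER).all()
        assert (result.best.genes <= GENE_UPPER).all()

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            rc.evolve([], config=GAConfig(seed=0))

    def test_threshold_only_ga_matches_exhaustive_search(self, known_params):
        """Reduced problem: with the color coefficients frozen, the GA's
        best threshold must tie exhaustive search over integer cuts 0-255."""
        spec = rc.SceneSpec(height=16, width=16, seed=9,
                            straw_length_range=(6, 12), straw_width_range=(3, 4),
                            vegetation_fraction=0.0, n_stones=1,
                            shadow_fraction=0.0)
        img, template = rc.generate_consistent_pair(known_params, spec=spec)
        coef = (known_params.c_r, known_params.c_g, known_params.c_b)

        exhaustive = min(
            rc.fitness(rc.segment(img, rc.SegmentationParams(*coef, t)), template)
            for t in range(256))
        assert exhaustive == 0.0  # consistent pair built from an integer cut

        result = rc.evolve(
            [(img, template)],
            config=GAConfig(seed=0, fitness_stop=None, max_generations=300),
            fixed_coefficients=coef)
        assert result.best.fitness == exhaustive
        np.testing.assert_array_equal(result.best.genes[:3], coef)
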