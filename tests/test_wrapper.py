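"""Hybrid-chromosome operators and the joint optimization loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_planted_classification
from ibfoml.optimizer import OptimizerConfig
from ibfoml.wrapper import (
    DEFAULT_SEARCH_SPACES,
    GaConfig,
    HybridChromosome,
    crossover,
    decode,
    fitness,
    mutate,
    optimize_model,
    repair,
    roulette_select,
)


def make_chrom(mask, genes, learner="LR"):
    return HybridChromosome(np.array(mask, dtype=bool), np.array(genes, dtype=float), learner)


class TestDecode:
    def test_log_scale_endpoints_and_midpoint(self):
        space = DEFAULT_SEARCH_SPACES["LR"]
        hp, _ = decode(make_chrom([1, 0], [0.0, 0.0]), space)
        assert hp["C"] == pytest.approx(1e-3)
        hp, _ = decode(make_chrom([1, 0], [1.0, 0.0]), space)
        assert hp["C"] == pytest.approx(100.0)
        hp, _ = decode(make_chrom([1, 0], [0.5, 0.0]), space)
        assert hp["C"] == pytest.approx(10 ** (-3 + 0.5 * 5), rel=1e-12)  # 0.31623

    def test_categorical_bucketing(self):
        space = DEFAULT_SEARCH_SPACES["LR"]
        hp, _ = decode(make_chrom([1], [0.0, 0.7]), space)
        assert hp["penalty"] == "L2"  # second of two equal bins
        hp, _ = decode(make_chrom([1], [0.0, 0.3]), space)
        assert hp["penalty"] == "L1"

    def test_bpnn_epochs_fixed(self):
        space = DEFAULT_SEARCH_SPACES["BPNN"]
        hp, _ = decode(make_chrom([1], [0.9, 0.5], "BPNN"), space)
        assert hp["epochs"] == 500
        assert hp["hidden"] in (16, 32, 64)

    @settings(max_examples=60, deadline=None)
    @given(genes=st.lists(st.floats(0, 1), min_size=3, max_size=3),
           learner=st.sampled_from(["XGBoost"]))
    def test_decoded_values_always_inside_declared_ranges(self, genes, learner):
        space = DEFAULT_SEARCH_SPACES[learner]
        hp, _ = decode(make_chrom([1, 1], genes, learner), space)
        assert 3 <= hp["max_depth"] <= 10 and isinstance(hp["max_depth"], int)
        assert 0.01 <= hp["learning_rate"] <= 0.3
        assert 0.5 <= hp["colsample_bytree"] <= 0.9


class TestOperators:
    def test_roulette_uniform_when_scores_equal(self):
        rng = np.random.default_rng(0)
        pop = [make_chrom([1], [0.5, 0.5]) for _ in range(4)]
        counts = np.zeros(4)
        for _ in range(10_000):
            a, _ = roulette_select(pop, [2.0, 2.0, 2.0, 2.0], rng)
            counts[next(i for i, c in enumerate(pop) if c is a)] += 1
        assert np.allclose(counts / 10_000, 0.25, atol=0.02)

    def test_roulette_proportional_to_score(self):
        rng = np.random.default_rng(1)
        pop = [make_chrom([1], [0.1, 0.1]), make_chrom([1], [0.9, 0.9])]
        first = sum(roulette_select(pop, [3.0, 1.0], rng)[0] is pop[0] for _ in range(10_000))
        assert first / 10_000 == pytest.approx(0.75, abs=0.02)

    def test_roulette_single_positive_always_chosen(self):
        rng = np.random.default_rng(2)
        pop = [make_chrom([1], [0.1]), make_chrom([1], [0.9]), make_chrom([1], [0.4])]
        for _ in range(200):
            a, b = roulette_select(pop, [0.0, 1.0, 0.0], rng)
            assert a is pop[1] and b is pop[1]

    def test_crossover_identical_parents_yield_identical_offspring(self):
        rng = np.random.default_rng(3)
        p = make_chrom([1, 0, 1, 1], [0.3, 0.6])
        a, b = crossover(p, p.copy(), GaConfig(), rng)
        assert np.array_equal(a.mask, p.mask) and np.array_equal(b.mask, p.mask)
        assert np.allclose(a.real_genes, p.real_genes)

    def test_crossover_offspring_in_parental_convex_hull(self):
        rng = np.random.default_rng(4)
        pa = make_chrom([1, 0, 1], [0.2, 0.8])
        pb = make_chrom([0, 1, 1], [0.4, 0.1])
        lo = np.minimum(pa.real_genes, pb.real_genes)
        hi = np.maximum(pa.real_genes, pb.real_genes)
        for _ in range(200):
            a, b = crossover(pa, pb, GaConfig(), rng)
            for child in (a, b):
                assert np.all(child.real_genes >= lo - 1e-12)
                assert np.all(child.real_genes <= hi + 1e-12)

    def test_mutate_noop_when_rates_zero(self):
        rng = np.random.default_rng(5)
        cfg = GaConfig(mutation_prob_bit=0.0, mutation_sigma_real=0.0)
        c = make_chrom([1, 0, 1], [0.3, 0.6])
        m = mutate(c, cfg, rng)
        assert np.array_equal(m.mask, c.mask) and np.array_equal(m.real_genes, c.real_genes)

    def test_bit_flip_rate_matches_binomial_mean(self):
        rng = np.random.default_rng(6)
        cfg = GaConfig()
        flips = 0
        trials = 10_000
        base = make_chrom([1, 0, 1, 0, 1, 0, 1], [0.5])
        for _ in range(trials):
            m = mutate(base, cfg, rng)
            flips += np.sum(m.mask != base.mask)
        # expected 7 * 0.02 = 0.14 flips per chromosome; repair may add a few
        assert flips / trials == pytest.approx(0.14, abs=0.02)

    def test_mutated_genes_stay_in_unit_interval(self):
        rng = np.random.default_rng(7)
        base = make_chrom([1, 1], [0.0, 1.0, 0.5])
        for _ in range(500):
            m = mutate(base, GaConfig(), rng)
            assert np.all((m.real_genes >= 0) & (m.real_genes <= 1))
            assert m.mask.any()

    def test_repair_enforces_nonempty_mask(self):
        rng = np.random.default_rng(8)
        c = HybridChromosome(np.zeros(5, dtype=bool), np.array([0.5]), "LR")
        assert repair(c, rng).mask.sum() == 1


class TestFitness:
    def test_sparsity_term_algebra(self, separable_data):
        X, y = separable_data
        cfg = GaConfig(cv_folds=4, w_perf=1.0, w_sparse=0.5)
        all_on = make_chrom([1, 1, 1], [0.8, 0.2])
        one_on = make_chrom([1, 0, 0], [0.8, 0.2])
        space = DEFAULT_SEARCH_SPACES["LR"]
        f_all = fitness(all_on, X, y, space, cfg, seed=0)
        f_one = fitness(one_on, X, y, space, cfg, seed=0)
        # both achieve F1 = 1 on separable data, so the scores differ exactly
        # by the sparsity bonus: 0.5 * (1/1 - 1/3)
        assert f_one - f_all == pytest.approx(0.5 * (1 - 1 / 3), abs=1e-9)

    def test_empty_mask_rejected(self, separable_data):
        X, y = separable_data
        c = HybridChromosome(np.zeros(3, dtype=bool), np.array([0.5, 0.5]), "LR")
        with pytest.raises(ValueError):
            fitness(c, X, y, DEFAULT_SEARCH_SPACES["LR"], GaConfig(cv_folds=4), seed=0)


class TestOptimizeModel:
    def test_history_monotone_and_seed_deterministic(self, separable_data):
        X, y = separable_data
        kwargs = dict(
            ga_config=GaConfig(cv_folds=4),
            optimizer_config=OptimizerConfig(population_size=6, max_iterations=4, seed=2),
        )
        r1 = optimize_model(X, y, "LR", **kwargs)
        r2 = optimize_model(X, y, "LR", **kwargs)
        assert np.all(np.diff(r1.history) >= 0)
        assert np.array_equal(r1.best_chromosome.mask, r2.best_chromosome.mask)
        assert np.array_equal(r1.best_chromosome.real_genes, r2.best_chromosome.real_genes)

    def test_recovers_planted_informative_features(self):
        """3 informative + 7 noise features: mask recall >= 0.8 in most seeds."""
        hits = 0
        for seed in range(5):
            X, y = make_planted_classification(300, 3, 7, seed=seed)
            res = optimize_model(
                X, y, "LR",
                ga_config=GaConfig(cv_folds=5),
                optimizer_config=OptimizerConfig(population_size=10, max_iterations=8, seed=seed),
            )
            recall = len(set(res.selected_indices) & {0, 1, 2}) / 3
            hits += recall >= 0.8
        assert hits >= 3
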