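"""Genetic operators, the evolutionary loop and the model/results API."""

import numpy as np
import pytest

from boolgp import (
    BooleanTreeGP,
    BoolTree,
    FitnessWeights,
    GPConfig,
    SENSITIVITY_WEIGHTS,
    fitness,
    init_population,
    run_gp,
    subtree_crossover,
    subtree_mutate,
    tournament_select,
)
from boolgp.trees import FUNCTIONS, random_tree
from conftest import bayes_pattern_bound


class TestFitness:
    def test_unweighted_equals_hamming_distance(self):
        X = np.eye(10, 4, dtype=np.int8)
        y = X[:, 0].copy()
        y[:3] ^= 1  # wrong on 3 of 10 rows for the identity tree
        assert fitness(BoolTree(0), X, y) == 3

    def test_weighted_example(self):
        # FN=2, FP=5 with weights (0.9, 0.1) -> 2.3
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0])
        X = np.array([[0], [0], [1], [1], [1], [1], [1], [0], [0]], dtype=np.int8)
        assert fitness(BoolTree(0), X, y, FitnessWeights(0.9, 0.1)) == pytest.approx(2.3)

    def test_perfect_predictions_zero_for_any_weights(self):
        X = np.array([[0], [1], [1]], dtype=np.int8)
        y = X[:, 0]
        for w in (FitnessWeights(), SENSITIVITY_WEIGHTS, FitnessWeights(5, 0.5)):
            assert fitness(BoolTree(0), X, y, w) == 0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            FitnessWeights(0, 0)
        with pytest.raises(ValueError):
            FitnessWeights(-1, 1)


class TestConfig:
    def test_rates_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GPConfig(crossover_rate=0.8, mutation_rate=0.1)

    def test_defaults_match_study_settings(self):
        cfg = GPConfig()
        assert (cfg.population_size, cfg.generations, cfg.tournament_size) == (500, 5, 10)
        assert (cfg.crossover_rate, cfg.mutation_rate) == (0.9, 0.1)


class TestInitPopulation:
    def test_population_size_exact(self):
        pop = init_population(GPConfig(population_size=137), 70, np.random.default_rng(0))
        assert len(pop) == 137

    def test_full_half_at_fixed_depth(self):
        cfg = GPConfig(population_size=40, init_depth_range=(2, 2))
        pop = init_population(cfg, 8, np.random.default_rng(3))
        # full/grow alternate per depth block; the full trees reach depth 2 exactly
        full_trees = pop[0::2]
        assert all(t.depth == 2 for t in full_trees)

    def test_reproducible_from_seed(self):
        cfg = GPConfig(population_size=30)
        a = init_population(cfg, 10, np.random.default_rng(5))
        b = init_population(cfg, 10, np.random.default_rng(5))
        assert [t.to_sexpr() for t in a] == [t.to_sexpr() for t in b]


class TestTournament:
    def test_strictly_best_sampled_individual_wins(self):
        pop = [BoolTree(i) for i in range(5)]
        fits = np.array([9.0, 9.0, 0.0, 9.0, 9.0])
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = tournament_select(pop, fits, k=5, rng=rng)
            if w.expr == 2:
                break
        # with k = n the best is sampled a.s. within a few draws
        assert w.expr == 2

    def test_uniform_among_ties(self):
        pop = [BoolTree(i) for i in range(4)]
        fits = np.zeros(4)
        rng = np.random.default_rng(1)
        winners = {tournament_select(pop, fits, 4, rng).expr for _ in range(200)}
        assert winners == {0, 1, 2, 3}

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            tournament_select([], np.array([]), 1, np.random.default_rng(0))


class TestVariation:
    def test_crossover_of_two_terminals(self):
        rng = np.random.default_rng(0)
        out = {
            subtree_crossover(BoolTree(1), BoolTree(2), 17, rng).expr for _ in range(50)
        }
        # enumerating crossover points: each parent has only its root, so the
        # sole offspring is the donor subtree X2; always within {X1, X2}
        assert out == {2}

    def test_crossover_depth_cap_holds(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            a = random_tree(rng, 6, 5, "grow")
            b = random_tree(rng, 6, 5, "grow")
            assert subtree_crossover(a, b, 6, rng).depth <= 6

    def test_mutation_preserves_validity_and_cap(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = random_tree(rng, 6, 5, "grow")
            child = subtree_mutate(a, 6, rng, n_features=6)
            assert child.depth <= 6
            # BoolTree construction re-validates arity; also check terminals
            assert max(child.terminals) < 6

    def test_mutation_reproducible(self):
        a = BoolTree.parse("(AND X1 (OR X2 X3))")
        c1 = subtree_mutate(a, 10, np.random.default_rng(9), n_features=5)
        c2 = subtree_mutate(a, 10, np.random.default_rng(9), n_features=5)
        assert c1.to_sexpr() == c2.to_sexpr()


class TestRunGP:
    def test_evaluation_budget_is_pop_times_gens(self):
        X = np.random.default_rng(0).integers(0, 2, (30, 5), dtype=np.int8)
        y = X[:, 1]
        run = run_gp(X, y, GPConfig(population_size=40, generations=3), seed=0)
        assert run.evaluations == 120

    def test_single_terminal_rule_solved(self, small_gp_config):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (60, 6), dtype=np.int8)
        y = X[:, 2]
        solved = sum(
            run_gp(X, y, small_gp_config, seed=s).train_fitness == 0 for s in range(10)
        )
        assert solved >= 8

    def test_deterministic_given_seed(self, small_gp_config, planted_ds):
        a = run_gp(planted_ds.features, planted_ds.labels, small_gp_config, seed=42)
        b = run_gp(planted_ds.features, planted_ds.labels, small_gp_config, seed=42)
        assert a.best_tree.to_sexpr() == b.best_tree.to_sexpr()
        assert a.train_fitness == b.train_fitness

    def test_features_used_match_tree_terminals(self, small_gp_config, planted_ds):
        run = run_gp(planted_ds.features, planted_ds.labels, small_gp_config, seed=1)
        assert run.features_used == run.best_tree.terminals

    def test_never_beats_bayes_pattern_bound(self, small_gp_config):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X = rng.integers(0, 2, (25, 3), dtype=np.int8)
            y = rng.integers(0, 2, 25, dtype=np.int8)
            if len(np.unique(y)) < 2:
                y[0] ^= 1
            run = run_gp(X, y, small_gp_config, seed=int(rng.integers(2**31)))
            assert run.train_fitness >= bayes_pattern_bound(X, y)

    def test_single_class_labels_warn(self, small_gp_config):
        X = np.random.default_rng(0).integers(0, 2, (20, 3), dtype=np.int8)
        with pytest.warns(UserWarning, match="single class"):
            run_gp(X, np.zeros(20, dtype=np.int8), small_gp_config, seed=0)

    def test_best_of_run_not_worse_than_initial_best(self, planted_ds):
        # best-ever tracking: the returned fitness cannot exceed the best of
        # the initial generation alone
        cfg1 = GPConfig(population_size=80, generations=1)
        cfg5 = GPConfig(population_size=80, generations=5)
        f1 = run_gp(planted_ds.features, planted_ds.labels, cfg1, seed=6).train_fitness
        f5 = run_gp(planted_ds.features, planted_ds.labels, cfg5, seed=6).train_fitness
        assert f5 <= f1


class TestModelAPI:
    def test_fit_returns_results_with_summary(self, planted_ds, small_gp_config):
        model = BooleanTreeGP(
            planted_ds.features,
            planted_ds.labels,
            config=small_gp_config,
            feature_names=planted_ds.gene_ids,
        )
        res = model.fit(seed=2)
        text = res.summary()
        assert "train fitness" in text and res.best_tree.to_sexpr() in text
        assert len(res.predict(planted_ds.features)) == planted_ds.n_patients
        cm = res.confusion(planted_ds.features, planted_ds.labels)
        assert cm.errors == res.train_fitness  # unweighted fitness == error count

    def test_from_dataframe_round_trip(self, planted_ds, small_gp_config):
        df = planted_ds.to_frame()
        model = BooleanTreeGP.from_dataframe(df, config=small_gp_config)
        assert model.X.shape == planted_ds.features.shape
        assert model.feature_names == planted_ds.gene_ids

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            BooleanTreeGP(np.array([[0.5, 1.0]]), np.array([1]))
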