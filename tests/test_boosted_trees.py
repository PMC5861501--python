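import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boostgrn import (
    BoostedEnsemble,
    LaggedProblem,
    ensemble_importance,
    fit_adaboost,
    fit_graboost,
    fit_regression_tree,
    tree_variable_importance,
)
from boostgrn.boosted_trees import FitError

from oracles import (
    assert_same_tree,
    oracle_adaboost_transcript,
    oracle_cart,
    oracle_tree_importance,
)


def make_problem(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = X.shape[1]
    return LaggedProblem(
        features=X, targets=y, regulator_indices=list(range(k)), target_index=k
    )


def random_problem(seed, n=30, k=4, signal=True):
    gen = np.random.default_rng(seed)
    X = gen.standard_normal((n, k))
    if signal:
        coefs = gen.standard_normal(k)
        y = X @ coefs + 0.3 * gen.standard_normal(n)
    else:
        y = gen.standard_normal(n)
    return make_problem(X, y)


class TestRegressionTree:
    def test_two_point_forced_split(self):
        tree = fit_regression_tree([[0.0], [1.0]], [0.0, 2.0], max_depth=1)
        root = tree.root
        assert root.feature == 0 and root.threshold == pytest.approx(0.5)
        assert root.left.value == 0.0 and root.right.value == 2.0
        np.testing.assert_array_equal(tree.predict([[-1.0], [3.0]]), [0.0, 2.0])

    def test_constant_targets_single_leaf(self, rng):
        X = rng.standard_normal((8, 2))
        tree = fit_regression_tree(X, np.full(8, 3.5), max_depth=3)
        assert tree.root.is_leaf and tree.root.value == 3.5

    def test_child_sample_counts_sum_to_parent(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        tree = fit_regression_tree(X, y, max_depth=3)
        for node in tree.internal_nodes():
            assert node.n_samples == node.left.n_samples + node.right.n_samples

    def test_matches_exhaustive_cart_on_six_points(self):
        X = np.array([[0.0, 5.0], [1.0, 4.0], [2.0, 3.0],
                      [3.0, 2.0], [4.0, 1.0], [5.0, 0.0]])
        y = np.array([0.0, 0.1, 2.0, 2.1, 5.0, 5.2])
        tree = fit_regression_tree(X, y, max_depth=2)
        assert_same_tree(tree.root, oracle_cart(X, y, max_depth=2))

    @given(seed=st.integers(0, 2**16))
    def test_matches_exhaustive_cart_randomized(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 13))
        k = int(gen.integers(1, 4))
        X = gen.standard_normal((n, k))
        y = gen.standard_normal(n)
        tree = fit_regression_tree(X, y, max_depth=2)
        assert_same_tree(tree.root, oracle_cart(X, y, max_depth=2))

    def test_weighted_fit_leaf_is_weighted_mean(self):
        X = np.array([[0.0], [0.0], [1.0]])
        y = np.array([0.0, 2.0, 10.0])
        w = np.array([3.0, 1.0, 1.0])
        tree = fit_regression_tree(X, y, sample_weights=w, max_depth=1)
        assert tree.root.left.value == pytest.approx(0.5)  # (3*0 + 1*2)/4


class TestVariableImportance:
    def test_hand_computed_two_sample_tree(self):
        tree = fit_regression_tree([[0.0], [1.0]], [0.0, 2.0], max_depth=1)
        # 2 * Var([0, 2]) - 0 - 0 = 2 * 1 = 2
        np.testing.assert_allclose(tree_variable_importance(tree), [2.0])

    def test_single_leaf_tree_all_zero(self, rng):
        tree = fit_regression_tree(rng.standard_normal((5, 3)), np.ones(5))
        np.testing.assert_array_equal(tree_variable_importance(tree), [0.0] * 3)

    def test_matches_per_node_recomputation(self, rng):
        X = rng.standard_normal((20, 4))
        y = X[:, 1] + 0.5 * rng.standard_normal(20)
        tree = fit_regression_tree(X, y, max_depth=3)
        np.testing.assert_allclose(
            tree_variable_importance(tree),
            oracle_tree_importance(tree, X, y),
            rtol=1e-9, atol=1e-12,
        )

    @given(seed=st.integers(0, 2**16))
    def test_variance_decomposition_telescopes(self, seed):
        """Sum of VIS equals root minus leaf weighted variances."""
        gen = np.random.default_rng(seed)
        n = int(gen.integers(4, 40))
        X = gen.standard_normal((n, 3))
        y = gen.standard_normal(n)
        tree = fit_regression_tree(X, y, max_depth=3)
        total = tree_variable_importance(tree).sum()
        root = tree.root
        leaves = sum(leaf.weight * leaf.variance for leaf in tree.leaves())
        np.testing.assert_allclose(
            total, root.weight * root.variance - leaves, rtol=1e-9, atol=1e-12
        )
        assert np.all(tree_variable_importance(tree) >= 0)


class TestAdaBoost:
    def test_round_bookkeeping_satisfies_estimator_weight_relation(self):
        prob = random_problem(0)
        ens = fit_adaboost(prob, n_rounds=20, learning_rate=0.7, seed=1)
        for rec, weight in zip(ens.trace, ens.estimator_weights):
            assert rec["beta"] == pytest.approx(
                rec["avg_loss"] / (1 - rec["avg_loss"])
            )
            assert weight == pytest.approx(0.7 * np.log(1 / rec["beta"]))
        assert np.all(ens.estimator_weights >= 0)

    def test_sample_weights_stay_positive_and_finite(self):
        prob = random_problem(3)
        ens = fit_adaboost(prob, n_rounds=50, seed=2)
        for rec in ens.trace:
            if "sample_weights" in rec:
                w = rec["sample_weights"]
                assert np.all(w > 0) and np.all(np.isfinite(w))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_transcript_matches_step_by_step_oracle(self, seed):
        prob = random_problem(seed, n=25, k=3)
        ens = fit_adaboost(prob, n_rounds=15, learning_rate=1.0, max_depth=2,
                           seed=seed)
        rounds, _ = oracle_adaboost_transcript(
            prob.features, prob.targets, 15, 1.0, 2, seed
        )
        assert len(rounds) == len(ens.trees)
        for rec, oracle_rec in zip(ens.trace, rounds):
            np.testing.assert_allclose(rec["avg_loss"], oracle_rec["avg_loss"],
                                       rtol=1e-12)
            np.testing.assert_allclose(rec["sample_weights"],
                                       oracle_rec["sample_weights"], rtol=1e-12)

    def test_perfectly_fittable_targets_halt_with_capped_weight(self):
        prob = make_problem([[0.0], [1.0], [2.0]], [5.0, 5.0, 5.0])
        ens = fit_adaboost(prob, n_rounds=10, seed=0)
        assert ens.n_rounds_completed == 1
        assert ens.trace[0]["halted"] == "zero_loss"
        assert ens.estimator_weights[0] == pytest.approx(np.log(1e10))

    @pytest.mark.parametrize("seed", range(8))
    def test_high_loss_halt_matches_oracle(self, seed):
        """Uninformative features force avg loss >= 0.5 in round one; the
        production halt/discard behavior mirrors the straight-line oracle."""
        X = np.zeros((2, 1))
        y = np.array([0.0, 1.0])
        prob = make_problem(X, y)
        try:
            rounds, halted = oracle_adaboost_transcript(X, y, 10, 1.0, 3, seed)
        except ValueError:
            with pytest.raises(FitError):
                fit_adaboost(prob, n_rounds=10, seed=seed)
            return
        ens = fit_adaboost(prob, n_rounds=10, seed=seed)
        assert ens.n_rounds_completed == len(rounds)
        assert ens.trace[-1].get("halted") == halted

    def test_seed_determinism(self):
        prob = random_problem(9)
        a = fit_adaboost(prob, n_rounds=10, seed=5)
        b = fit_adaboost(prob, n_rounds=10, seed=5)
        np.testing.assert_array_equal(a.estimator_weights, b.estimator_weights)
        np.testing.assert_array_equal(
            ensemble_importance(a), ensemble_importance(b)
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(FitError):
            fit_adaboost(make_problem([[1.0]], [1.0]), n_rounds=5)


class TestGraBoost:
    def test_initial_estimator_is_target_mean(self):
        prob = make_problem([[0.0], [1.0], [2.0]], [1.0, 2.0, 3.0])
        ens = fit_graboost(prob, n_rounds=1)
        assert ens.init_value == 2.0

    def test_full_depth_unit_rate_interpolates_in_one_round(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        prob = make_problem(X, y)
        ens = fit_graboost(prob, n_rounds=1, learning_rate=1.0, max_depth=10)
        np.testing.assert_allclose(ens.predict(X), y, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_training_mse_non_increasing(self, seed):
        prob = random_problem(seed, n=40, k=3)
        X, y = prob.features, prob.targets
        pred = np.full(len(y), y.mean())
        ens = fit_graboost(prob, n_rounds=100, learning_rate=0.1)
        prev_mse = np.mean((y - pred) ** 2)
        for tree in ens.trees:
            pred = pred + 0.1 * tree.predict(X)
            mse = np.mean((y - pred) ** 2)
            assert mse <= prev_mse + 1e-12
            prev_mse = mse

    def test_deterministic_without_seed_dependence(self):
        prob = random_problem(11)
        a = fit_graboost(prob, n_rounds=10, seed=0)
        b = fit_graboost(prob, n_rounds=10, seed=999)
        np.testing.assert_array_equal(a.predict(prob.features),
                                      b.predict(prob.features))


class TestEnsembleImportance:
    def _orthogonal_trees(self):
        t1 = fit_regression_tree([[0.0, 9.0], [1.0, 9.0]], [0.0, 2.0], max_depth=1)
        t2 = fit_regression_tree([[9.0, 0.0], [9.0, 1.0]], [0.0, 2.0], max_depth=1)
        return t1, t2  # VIS vectors [2, 0] and [0, 2]

    def test_adaboost_weighted_sum(self):
        t1, t2 = self._orthogonal_trees()
        ens = BoostedEnsemble(
            trees=[t1, t2], estimator_weights=[np.log(2), np.log(2)],
            method="adaboost", learning_rate=1.0, n_features=2,
        )
        np.testing.assert_allclose(
            ensemble_importance(ens, normalize=False),
            [2 * np.log(2), 2 * np.log(2)],
        )
        np.testing.assert_allclose(ensemble_importance(ens), [0.5, 0.5])

    def test_graboost_average_is_fixed_point_for_identical_trees(self):
        t1, _ = self._orthogonal_trees()
        ens = BoostedEnsemble(
            trees=[t1, t1, t1], estimator_weights=[0.1] * 3,
            method="graboost", learning_rate=0.1, n_features=2, init_value=0.0,
        )
        np.testing.assert_allclose(
            ensemble_importance(ens, normalize=False),
            tree_variable_importance(t1),
        )

    def test_normalized_importance_sums_to_one(self):
        prob = random_problem(13)
        for ens in (fit_adaboost(prob, n_rounds=10, seed=0),
                    fit_graboost(prob, n_rounds=10)):
            vis = ensemble_importance(ens)
            assert vis.sum() == pytest.approx(1.0)
            assert np.all(vis >= 0)

    def test_empty_ensemble_rejected(self):
        ens = BoostedEnsemble(trees=[], estimator_weights=[], method="adaboost",
                              learning_rate=1.0, n_features=2)
        with pytest.raises(ValueError):
            ensemble_importance(ens)
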