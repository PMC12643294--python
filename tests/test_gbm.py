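"""Boosted regression trees and interventional Shapley attribution."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from defauna.gbm import (
    GBMParams,
    GBTResults,
    GradientBoostedTrees,
    RegressionTree,
    evaluate,
    shap_values,
    split_data,
    tune_random_search,
)


class TestSplitData:
    def test_sizes_75_25(self):
        df = pd.DataFrame({"x": range(100)})
        train, test = split_data(df, 0.75, seed=0)
        assert len(train) == 75 and len(test) == 25

    def test_partition_and_determinism(self):
        df = pd.DataFrame({"x": range(40)})
        t1, h1 = split_data(df, seed=3)
        t2, h2 = split_data(df, seed=3)
        assert sorted(t1.x) == sorted(t2.x)
        assert set(t1.x) | set(h1.x) == set(range(40))
        assert not set(t1.x) & set(h1.x)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_data(pd.DataFrame({"x": range(5)}))


class TestRegressionTree:
    def test_stump_recovers_step_function(self):
        x = np.linspace(0, 1, 50).reshape(-1, 1)
        y = (x[:, 0] > 0.5).astype(float)
        tree = RegressionTree(max_depth=1, min_node=1).fit(x, y)
        pred = tree.predict(x)
        np.testing.assert_allclose(pred, y)

    def test_tie_break_lowest_feature_index(self):
        # two identical features; the split must use feature 0
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        y = (x[:, 0] > 4.5).astype(float)
        tree = RegressionTree(max_depth=1, min_node=1).fit(x, y)
        assert tree.feature[0] == 0

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(30)
        x = rng.random((40, 3))
        y = rng.random(40)
        tree = RegressionTree(max_depth=3, min_node=2).fit(x, y)
        back = RegressionTree.from_dict(tree.to_dict())
        np.testing.assert_array_equal(tree.predict(x), back.predict(x))


class TestBoosting:
    def test_zero_trees_predicts_mean(self):
        x = np.random.default_rng(31).random((20, 2))
        y = np.arange(20.0)
        res = GradientBoostedTrees(x, y).fit(GBMParams(n_trees=0))
        np.testing.assert_allclose(res.predict(x), y.mean())

    def test_single_stump_full_shrinkage_recovers_step(self):
        x = np.linspace(0, 1, 30).reshape(-1, 1)
        y = (x[:, 0] > 0.5).astype(float) * 4.0
        res = GradientBoostedTrees(x, y).fit(
            GBMParams(n_trees=1, depth=1, learning_rate=1.0, subsample=1.0,
                      min_node=1)
        )
        np.testing.assert_allclose(res.predict(x), y, atol=1e-12)

    def test_half_shrinkage_moves_halfway(self):
        x = np.array([[0.0], [1.0]])
        y = np.array([0.0, 2.0])
        res = GradientBoostedTrees(x, y).fit(
            GBMParams(n_trees=1, depth=1, learning_rate=0.5, subsample=1.0,
                      min_node=1)
        )
        np.testing.assert_allclose(res.predict(x), [0.5, 1.5])

    def test_training_mse_monotone_without_subsampling(self):
        rng = np.random.default_rng(32)
        x = rng.random((80, 4))
        y = np.sin(3 * x[:, 0]) + x[:, 1] ** 2 + 0.1 * rng.normal(size=80)
        res = GradientBoostedTrees(x, y).fit(
            GBMParams(n_trees=60, depth=2, learning_rate=0.2, subsample=1.0)
        )
        assert np.all(np.diff(res.train_mse_path) <= 1e-12)

    def test_constant_response_warns_empty_ensemble(self):
        x = np.random.default_rng(33).random((10, 2))
        with pytest.warns(UserWarning, match="constant"):
            res = GradientBoostedTrees(x, np.ones(10)).fit(GBMParams(n_trees=50))
        assert len(res.trees) == 0

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(34)
        x = rng.random((60, 3))
        y = rng.random(60)
        p = GBMParams(n_trees=20, depth=2, subsample=0.7)
        r1 = GradientBoostedTrees(x, y).fit(p, seed=5).predict(x)
        r2 = GradientBoostedTrees(x, y).fit(p, seed=5).predict(x)
        np.testing.assert_array_equal(r1, r2)

    def test_ensemble_json_round_trip(self):
        rng = np.random.default_rng(35)
        x = rng.random((50, 3))
        y = rng.random(50)
        res = GradientBoostedTrees(x, y).fit(GBMParams(n_trees=10, depth=2))
        back = GBTResults.from_json(res.to_json())
        np.testing.assert_allclose(res.predict(x), back.predict(x))

    def test_against_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.ensemble")
        rng = np.random.default_rng(36)
        x = rng.random((200, 3))
        y = 3 * x[:, 0] + np.sin(5 * x[:, 1]) + 0.05 * rng.normal(size=200)
        params = GBMParams(n_trees=150, depth=2, learning_rate=0.1, subsample=1.0,
                           min_node=2)
        ours = GradientBoostedTrees(x, y).fit(params)
        ref = sklearn.GradientBoostingRegressor(
            n_estimators=150, max_depth=2, learning_rate=0.1, subsample=1.0,
            min_samples_leaf=2,
        ).fit(x, y)
        r2_ours = evaluate(ours, x, y)["r2"]
        from sklearn.metrics import r2_score

        r2_ref = r2_score(y, ref.predict(x))
        assert r2_ours == pytest.approx(r2_ref, abs=0.05)


class TestEvaluate:
    def test_perfect_predictions(self):
        x = np.linspace(0, 1, 30).reshape(-1, 1)
        y = (x[:, 0] > 0.5) * 2.0
        res = GradientBoostedTrees(x, y).fit(
            GBMParams(n_trees=1, depth=1, learning_rate=1.0, min_node=1)
        )
        m = evaluate(res, x, y)
        assert m["r2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_prediction_r2_zero(self):
        x = np.random.default_rng(37).random((20, 1))
        y = np.arange(20.0)
        res = GradientBoostedTrees(x, y).fit(GBMParams(n_trees=0))
        assert evaluate(res, x, y)["r2"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        x = np.array([[0.0], [1.0]])
        res = GradientBoostedTrees(x, np.array([1.0, 1.0]))
        fitted = res.fit(GBMParams(n_trees=0))
        m = evaluate(fitted, x, np.array([0.0, 2.0]))
        assert m["rmse"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(0.0)

    def test_zero_variance_target_r2_missing(self):
        x = np.array([[0.0], [1.0]])
        fitted = GradientBoostedTrees(x, np.array([0.0, 2.0])).fit(GBMParams(n_trees=0))
        assert evaluate(fitted, x, np.array([1.0, 1.0]))["r2"] is None


class TestTuning:
    def test_single_candidate_selected(self):
        rng = np.random.default_rng(38)
        x = rng.random((30, 2))
        y = x[:, 0]
        cv = tune_random_search(x, y, n_candidates=1, k=3, seed=0)
        assert cv.selected == cv.candidates[0]

    def test_more_trees_win_on_linear_signal(self):
        rng = np.random.default_rng(39)
        x = rng.random((120, 1))
        y = 3 * x[:, 0] + 0.05 * rng.normal(size=120)
        space_big = {"n_trees": (200, 200), "depth": (1,),
                     "learning_rate": (0.1, 0.1), "subsample": (1.0, 1.0)}
        space_small = {"n_trees": (1, 1), "depth": (1,),
                       "learning_rate": (0.1, 0.1), "subsample": (1.0, 1.0)}
        cv_big = tune_random_search(x, y, space=space_big, n_candidates=1, k=5, seed=1)
        cv_small = tune_random_search(x, y, space=space_small, n_candidates=1, k=5,
                                      seed=1)
        assert min(cv_big.cv_rmse) < min(cv_small.cv_rmse)

    def test_determinism(self):
        rng = np.random.default_rng(40)
        x = rng.random((40, 2))
        y = rng.random(40)
        cv1 = tune_random_search(x, y, n_candidates=4, k=4, seed=9)
        cv2 = tune_random_search(x, y, n_candidates=4, k=4, seed=9)
        assert cv1.cv_rmse == cv2.cv_rmse
        assert cv1.selected == cv2.selected

    def test_recovery_at_4_to_1_signal_to_noise(self):
        rng = np.random.default_rng(41)
        n = 400
        x = rng.random((n, 4))
        signal = np.sin(4 * x[:, 0]) + 2 * x[:, 1]
        noise = rng.normal(size=n) * (signal.std() / 2.0)  # var ratio 4:1
        y = signal + noise
        df = pd.DataFrame(x, columns=list("abcd"))
        df["y"] = y
        train, test = split_data(df, 0.75, seed=2)
        cv = tune_random_search(
            train, "y", n_candidates=8, k=5, seed=2,
            test=(test[list("abcd")].to_numpy(), test["y"].to_numpy()),
        )
        assert cv.test_metrics["r2"] > 0.6


def brute_force_shapley(results, x_row, bg):
    """Independent Shapley oracle: direct permutation average."""
    d = x_row.size
    phi = np.zeros(d)
    for perm in itertools.permutations(range(d)):
        hybrid = bg.copy()
        prev = results.predict(hybrid).mean()
        for j in perm:
            hybrid[:, j] = x_row[j]
            cur = results.predict(hybrid).mean()
            phi[j] += cur - prev
            prev = cur
    return phi / math.factorial(d)


class TestShap:
    def _additive_results(self):
        # hand-built additive ensemble: one stump on each of two features
        t1 = RegressionTree(1, 1)
        t1.feature, t1.threshold = [0, -1, -1], [0.5, 0, 0]
        t1.left, t1.right = [1, -1, -1], [2, -1, -1]
        t1.value = [0.0, 0.0, 4.0]
        t2 = RegressionTree(1, 1)
        t2.feature, t2.threshold = [1, -1, -1], [0.5, 0, 0]
        t2.left, t2.right = [1, -1, -1], [2, -1, -1]
        t2.value = [0.0, 0.0, 10.0]
        rng = np.random.default_rng(42)
        x = rng.random((40, 3))
        model = GradientBoostedTrees(x, np.zeros(40))
        return GBTResults(model, GBMParams(learning_rate=1.0), 0.0, [t1, t2],
                          np.empty(0), 0)

    def test_unused_feature_gets_zero(self):
        res = self._additive_results()
        expl = shap_values(res, res.model.X[:5], background=res.model.X)
        np.testing.assert_allclose(expl.values[:, 2], 0.0, atol=1e-12)

    def test_additivity_decomposition(self):
        res = self._additive_results()
        x = res.model.X
        expl = shap_values(res, x[:8], background=x)
        g = 4.0 * (x[:8, 0] > 0.5)
        h = 10.0 * (x[:8, 1] > 0.5)
        g_mean = (4.0 * (x[:, 0] > 0.5)).mean()
        h_mean = (10.0 * (x[:, 1] > 0.5)).mean()
        np.testing.assert_allclose(expl.values[:, 0], g - g_mean, atol=1e-10)
        np.testing.assert_allclose(expl.values[:, 1], h - h_mean, atol=1e-10)

    def test_local_accuracy(self):
        rng = np.random.default_rng(43)
        x = rng.random((30, 4))
        y = x[:, 0] * 2 + np.sin(4 * x[:, 1]) + x[:, 2] * x[:, 3]
        res = GradientBoostedTrees(x, y).fit(GBMParams(n_trees=40, depth=3))
        expl = shap_values(res, x[:6], background=x)
        np.testing.assert_allclose(expl.local_accuracy_gap(res), 0.0, atol=1e-9)

    def test_symmetry_for_interchangeable_features(self):
        # the Shapley symmetry axiom needs the value function symmetric in
        # the two features, so build an ensemble using both identically:
        # one stump on feature 0 plus an identical stump on feature 1
        def stump(feature):
            t = RegressionTree(1, 1)
            t.feature, t.threshold = [feature, -1, -1], [0.5, 0, 0]
            t.left, t.right = [1, -1, -1], [2, -1, -1]
            t.value = [0.0, 0.0, 5.0]
            return t

        rng = np.random.default_rng(44)
        base = rng.random(50)
        x = np.column_stack([base, base])
        model = GradientBoostedTrees(x, np.zeros(50))
        res = GBTResults(model, GBMParams(learning_rate=1.0), 0.0,
                         [stump(0), stump(1)], np.empty(0), 0)
        expl = shap_values(res, x[:5], background=x)
        np.testing.assert_allclose(expl.values[:, 0], expl.values[:, 1], atol=1e-9)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(45)
        x = rng.random((25, 3))
        y = x[:, 0] + 2 * x[:, 1] * x[:, 2]
        res = GradientBoostedTrees(x, y).fit(GBMParams(n_trees=15, depth=2))
        expl = shap_values(res, x[:3], background=x)
        for i in range(3):
            oracle = brute_force_shapley(res, x[i], x.copy())
            np.testing.assert_allclose(expl.values[i], oracle, atol=1e-9)

    def test_sampling_close_to_exact(self):
        rng = np.random.default_rng(46)
        x = rng.random((30, 3))
        y = x[:, 0] * 3 + x[:, 1]
        res = GradientBoostedTrees(x, y).fit(GBMParams(n_trees=20, depth=2))
        exact = shap_values(res, x[:4], background=x, method="exact")
        sampled = shap_values(res, x[:4], background=x, method="sampling",
                              n_perm=400, seed=1)
        np.testing.assert_allclose(sampled.values, exact.values, atol=0.05)
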