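import dataclasses

import numpy as np
import pytest

from minkograde import (
    FEATURE_NAMES,
    FeatureVector,
    GPClassifier,
    GPConfig,
    GPModel,
    DEFAULT_PARAM_GRID,
    cross_validate,
    evaluate_tree,
    gp_train,
    grid_search,
)
from minkograde.gp import Node, _random_tree


def reference_interpreter(node, x):
    """Independent recursive-descent evaluation on one sample (pure
    Python scalars)."""
    op = node.op
    if op == "feat":
        return float(x[node.feature])
    if op == "const":
        return float(node.value)
    kids = [reference_interpreter(c, x) for c in node.children]
    if op == "add":
        return kids[0] + kids[1]
    if op == "sub":
        return kids[0] - kids[1]
    if op == "mul":
        return kids[0] * kids[1]
    if op == "div":
        return 1.0 if kids[1] == 0 else kids[0] / kids[1]
    if op == "lt":
        return kids[0] < kids[1]
    if op == "le":
        return kids[0] <= kids[1]
    if op == "gt":
        return kids[0] > kids[1]
    if op == "ge":
        return kids[0] >= kids[1]
    if op == "not":
        return not kids[0]
    if op == "and":
        return kids[0] and kids[1]
    if op == "or":
        return kids[0] or kids[1]
    return kids[0] != kids[1]  # xor


def make_fv(values, sample_id="s", label=None):
    feats = dict(zip(FEATURE_NAMES, np.zeros(15)))
    feats.update(values)
    return FeatureVector(sample_id=sample_id, features=feats, label=label)


def separable_dataset(n_per_class=20, margin=1.0, seed=0):
    rng = np.random.default_rng(seed)
    neg = rng.uniform(-5, -margin / 2, n_per_class)
    pos = rng.uniform(margin / 2, 5, n_per_class)
    X = np.concatenate([neg, pos]).reshape(-1, 1)
    y = np.array(["gradeII"] * n_per_class + ["gradeIV"] * n_per_class)
    return X, y


class TestEvaluation:
    def test_single_comparison(self):
        tree = Node(
            "lt",
            [Node("feat", feature=0), Node("const", value=-700.0)],
        )
        model = GPModel(tree=tree)
        fv = make_fv({"euler_min": -905.0})
        # -905 < -700 is True -> positive class (grade IV)
        assert evaluate_tree(model, fv) == "gradeIV"

    def test_negation(self):
        inner = Node(
            "lt",
            [Node("feat", feature=0), Node("const", value=-700.0)],
        )
        model = GPModel(tree=Node("not", [inner]))
        fv = make_fv({"euler_min": -905.0})
        assert evaluate_tree(model, fv) == "gradeII"

    def test_random_trees_match_reference_interpreter(self, rng):
        ranges = np.tile([-10.0, 10.0], (15, 1))
        X = rng.normal(size=(20, 15)) * 5
        for _ in range(100):
            tree = _random_tree(rng, ranges, "bool", 6, 40)
            model = GPModel(tree=tree)
            fast = model.predict(X)
            slow = np.array(
                [bool(reference_interpreter(tree, x)) for x in X]
            )
            assert np.array_equal(fast, slow)

    def test_ill_typed_tree_rejected_at_construction(self):
        real_leaf = Node("const", value=1.0)
        with pytest.raises(ValueError):
            Node("and", [real_leaf, real_leaf])  # AND needs Booleans
        cmp_node = Node("lt", [real_leaf, Node("const", value=2.0)])
        with pytest.raises(ValueError):
            Node("add", [cmp_node, real_leaf])  # + needs reals

    def test_model_json_round_trip(self, rng):
        ranges = np.tile([-1.0, 1.0], (15, 1))
        tree = _random_tree(rng, ranges, "bool", 5, 30)
        model = GPModel(tree=tree, training_accuracy=0.75)
        back = GPModel.from_json(model.to_json())
        X = rng.normal(size=(10, 15))
        assert np.array_equal(model.predict(X), back.predict(X))
        assert str(model) == str(back)


class TestTraining:
    def test_separable_problem_single_seed(self):
        X, y = separable_dataset()
        cfg = GPConfig(max_generations=70, max_tree_length=25, seed=5)
        model = gp_train(X, y, cfg, feature_names=["f1"])
        assert model.training_accuracy == 1.0

    def test_coin_flip_training_beats_majority(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        y = rng.random(100) < 0.5
        y[:2], y[-2:] = True, False
        cfg = GPConfig(max_generations=20, seed=1)
        model = gp_train(X, y, cfg, feature_names=["a", "b", "c"])
        assert model.training_accuracy > 0.5

    def test_same_seed_gives_identical_model(self):
        X, y = separable_dataset(seed=2)
        cfg = GPConfig(max_generations=30, seed=9)
        m1 = gp_train(X, y, cfg, feature_names=["f1"])
        m2 = gp_train(X, y, cfg, feature_names=["f1"])
        assert m1.to_json() == m2.to_json()

    def test_single_class_rejected(self):
        X = np.zeros((10, 1))
        y = np.array(["gradeII"] * 10)
        with pytest.raises(ValueError):
            gp_train(X, y, GPConfig(), feature_names=["f1"])

    def test_tree_limits_respected(self):
        X, y = separable_dataset(seed=4)
        cfg = GPConfig(
            max_generations=15, max_tree_depth=4, max_tree_length=10, seed=0
        )
        model = gp_train(X, y, cfg, feature_names=["f1"])
        assert model.depth <= 4
        assert model.length <= 10


class TestCrossValidation:
    def test_separable_recovery(self):
        X, y = separable_dataset()
        cfg = GPConfig(
            max_generations=70, max_tree_length=25, n_folds=5, n_runs=3,
            seed=0,
        )
        res = cross_validate(X, y, cfg, feature_names=["f1"])
        assert res.best_run_accuracy >= 0.95

    def test_leave_one_out_partitions_data(self):
        X, y = separable_dataset(n_per_class=6)
        cfg = GPConfig(
            max_generations=10, n_folds=12, n_runs=1, seed=0
        )
        res = cross_validate(X, y, cfg, feature_names=["f1"])
        assert res.fold_accuracies.shape == (1, 12)

    def test_class_smaller_than_folds_rejected(self):
        X, y = separable_dataset(n_per_class=4)
        cfg = GPConfig(n_folds=10, n_runs=1)
        with pytest.raises(ValueError):
            cross_validate(X, y, cfg, feature_names=["f1"])

    def test_no_leakage_from_test_labels(self):
        X, y = separable_dataset(n_per_class=10, seed=6)
        ybin = y == "gradeIV"
        idx = np.arange(len(y))
        folds = [(idx[:14], idx[14:]), (idx[6:], idx[:6])]
        cfg = GPConfig(max_generations=15, n_runs=2, seed=3)
        res1 = cross_validate(X, ybin, cfg, folds=folds,
                              feature_names=["f1"])
        poisoned = ybin.copy()
        poisoned[14:] = ~poisoned[14:]  # corrupt fold-1 test labels only
        res2 = cross_validate(X, poisoned, cfg, folds=folds,
                              feature_names=["f1"])
        # fold 0 trains on samples 0..13 with identical labels and an
        # identical rng stream in both runs: the trained model must not
        # depend on the (poisoned) test-fold labels
        for r in range(2):
            assert (
                res1.fold_models[r][0].to_json()
                == res2.fold_models[r][0].to_json()
            )


class TestGridSearch:
    def test_single_configuration_equals_cross_validate(self):
        X, y = separable_dataset(seed=1)
        cfg = GPConfig(n_folds=4, n_runs=2, seed=10)
        grid = {"max_generations": (25,)}
        ranked = grid_search(X, y, cfg, grid=grid)
        assert len(ranked) == 1
        sub, res = ranked[0]
        direct = cross_validate(
            X, y, dataclasses.replace(cfg, max_generations=25, seed=10)
        )
        assert np.array_equal(res.fold_accuracies, direct.fold_accuracies)

    def test_full_grid_is_ranked_permutation(self):
        X, y = separable_dataset(n_per_class=20, seed=8)
        cfg = GPConfig(n_folds=10, n_runs=2, seed=0)
        ranked = grid_search(X, y, cfg)
        n_expected = int(
            np.prod([len(v) for v in DEFAULT_PARAM_GRID.values()])
        )
        assert len(ranked) == n_expected == 24
        accs = [res.best_run_accuracy for _, res in ranked]
        assert accs == sorted(accs, reverse=True)
        # separable toy problem solved across the whole grid
        assert all(acc >= 0.95 for acc in accs)


class TestModelResultsSurface:
    def test_fit_summary_and_predict(self):
        X, y = separable_dataset(seed=12)
        clf = GPClassifier(
            X, y, feature_names=["f1"],
            config=GPConfig(max_generations=40, seed=2),
        )
        res = clf.fit()
        text = res.summary()
        assert "training accuracy" in text and "f1" in str(res.model)
        pred = res.predict(np.array([[-4.0], [4.0]]))
        assert list(pred) == ["gradeII", "gradeIV"]

    def test_from_dataframe(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(size=(24, 15)), columns=list(FEATURE_NAMES)
        )
        df["label"] = ["gradeII", "gradeIV"] * 12
        df.loc[df.label == "gradeIV", "euler_min"] += 30.0
        clf = GPClassifier.from_dataframe(
            df, config=GPConfig(max_generations=30, seed=0)
        )
        res = clf.fit()
        assert res.model.training_accuracy >= 0.9
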