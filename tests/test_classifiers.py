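"""Published threshold/tree rules and the CART trainer (Gini splits,
direct-stop rule, cross-validation costs)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fetquant.classifiers import (
    ASTROGLIOSIS,
    TUMOR,
    CartClassifier,
    CartParams,
    CartTree,
    DualPlexusClassifier,
    PublishedTreeClassifier,
    ThresholdClassifier,
    ThresholdRule,
    apply_threshold_rule,
    dual_plexus_rule,
    fit_cart,
    predict_cart,
    published_tree_classify,
    thalamus_rule,
)


class TestThresholdRules:
    def test_brain_16_rule(self):
        rule = ThresholdRule("tbr_brain_10", 1.6)
        assert apply_threshold_rule({"tbr_brain_10": 1.7}, rule) == TUMOR
        assert apply_threshold_rule({"tbr_brain_10": 1.5}, rule) == ASTROGLIOSIS

    def test_strict_boundary_is_astrogliosis(self):
        rule = ThresholdRule("tbr_plexus_roimean_10", 1.0)
        assert apply_threshold_rule({"tbr_plexus_roimean_10": 1.0}, rule) == ASTROGLIOSIS

    def test_late_plexus_rule(self):
        rule = ThresholdRule("tbr_plexus_60", 1.2)
        assert apply_threshold_rule({"tbr_plexus_60": 1.3}, rule) == TUMOR

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError, match="unknown feature"):
            apply_threshold_rule({"x": 1.0}, ThresholdRule("y", 1.0))

    def test_monotone_in_feature_value(self):
        rule = ThresholdRule("f", 1.5)
        labels = [apply_threshold_rule({"f": v}, rule) for v in np.linspace(0.1, 3.0, 50)]
        # once tumor, always tumor as the value rises
        first_tumor = labels.index(TUMOR)
        assert all(lbl == TUMOR for lbl in labels[first_tumor:])


class TestDualPlexusRule:
    @pytest.mark.parametrize(
        "early,late,expected",
        [
            (1.2, 1.0, TUMOR),  # early branch fires
            (0.9, 1.3, TUMOR),  # late branch fires
            (0.9, 1.0, ASTROGLIOSIS),  # neither fires
        ],
    )
    def test_disjunction(self, early, late, expected):
        row = {"tbr_plexus_10": early, "tbr_plexus_60": late}
        assert dual_plexus_rule(row) == expected

    def test_missing_feature_rejected(self):
        with pytest.raises(KeyError):
            dual_plexus_rule({"tbr_plexus_10": 1.0})

    def test_never_less_sensitive_than_late_alone(self, rng):
        """The union can only add tumor calls relative to the late rule."""
        for _ in range(100):
            row = {
                "tbr_plexus_10": rng.uniform(0.2, 3.0),
                "tbr_plexus_60": rng.uniform(0.2, 3.0),
            }
            late_only = TUMOR if row["tbr_plexus_60"] > 1.2 else ASTROGLIOSIS
            if late_only == TUMOR:
                assert dual_plexus_rule(row) == TUMOR


class TestPublishedTree:
    @pytest.mark.parametrize(
        "tbr,module,expected",
        [
            (2.0, 1.5, TUMOR),  # high-plexus branch
            (1.5, 1.0, TUMOR),  # intermediate branch
            (0.9, 5.0, ASTROGLIOSIS),  # below both branches
            (2.0, 1.0, ASTROGLIOSIS),  # high plexus but module too small
            (1.5, 3.5, ASTROGLIOSIS),  # intermediate plexus, module too large
            (1.77, 1.0, TUMOR),  # boundary 1.77 belongs to the second branch
            (1.05, 1.0, ASTROGLIOSIS),  # boundary 1.05 stays below the branch
        ],
    )
    def test_decision_regions(self, tbr, module, expected):
        assert published_tree_classify(tbr, module) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            published_tree_classify(-0.1, 1.0)

    def test_partitions_plane(self, rng):
        for _ in range(200):
            label = published_tree_classify(rng.uniform(0, 4), rng.uniform(0, 5))
            assert label in (TUMOR, ASTROGLIOSIS)


class TestThalamusRule:
    def test_relative_late_inclusive(self):
        assert thalamus_rule(1.6, 60, "relative") == "pathological"
        assert thalamus_rule(1.59, 60, "relative") == "normal"

    def test_absolute_late_threshold(self):
        assert thalamus_rule(1.05, 60, "absolute") == "normal"
        assert thalamus_rule(1.15, 60, "absolute") == "pathological"

    def test_absolute_early_threshold(self):
        assert thalamus_rule(1.05, 10, "absolute") == "pathological"

    def test_zero_is_normal(self):
        assert thalamus_rule(0.0, 60, "absolute") == "normal"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            thalamus_rule(1.0, 60, "bogus")


def brute_force_best_split(X, y):
    """Exhaustive oracle: best (feature, midpoint) by Gini decrease."""

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return 1.0 - np.sum(p**2)

    n = len(y)
    parent = gini(y)
    best = (None, None, -np.inf)
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            dec = parent - len(left) / n * gini(left) - len(right) / n * gini(right)
            if dec > best[2] + 1e-12:
                best = (f, thr, dec)
    return best


class TestCart:
    def test_one_dimensional_midpoint_split(self):
        X = np.array([[1.0], [2.0], [4.0], [5.0]])
        y = np.array([ASTROGLIOSIS, ASTROGLIOSIS, TUMOR, TUMOR])
        tree = fit_cart(X, y, CartParams(cv_folds=2, seed=0))
        assert tree.root.threshold == pytest.approx(3.0)
        assert tree.resubstitution_cost == 0.0

    def test_pure_input_single_leaf(self):
        X = np.array([[1.0], [2.0], [3.0]])
        tree = fit_cart(X, np.array([TUMOR] * 3), CartParams(cv_folds=2))
        assert tree.root.is_leaf
        assert tree.resubstitution_cost == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_cart(np.empty((0, 2)), np.array([]))

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="missing"):
            fit_cart(X, np.array([TUMOR, ASTROGLIOSIS]))

    def test_split_matches_brute_force_oracle(self, rng):
        """The chosen root split's Gini decrease equals an exhaustive search
        over all features x midpoints."""
        for trial in range(25):
            n = int(rng.integers(10, 200))
            d = int(rng.integers(1, 5))
            X = rng.normal(size=(n, d)).round(2)  # rounding forces ties
            y = np.where(rng.random(n) < 0.5, TUMOR, ASTROGLIOSIS)
            if len(np.unique(y)) < 2:
                continue
            tree = fit_cart(X, y, CartParams(min_node_fraction=0.4, cv_folds=2, seed=1))
            f, thr, dec = brute_force_best_split(X, y)
            if tree.root.is_leaf:
                assert dec <= 1e-12
            else:
                root_f = tree.feature_names.index(tree.root.feature)
                # equal decrease; the tree's tie-break may pick another split
                left = y[X[:, root_f] <= tree.root.threshold]
                right = y[X[:, root_f] > tree.root.threshold]

                def gini(labels):
                    _, c = np.unique(labels, return_counts=True)
                    p = c / c.sum()
                    return 1.0 - np.sum(p**2)

                got = gini(y) - len(left) / n * gini(left) - len(right) / n * gini(right)
                assert got == pytest.approx(dec, abs=1e-9)

    def test_permuted_labels_cv_worse_than_resubstitution(self):
        """With labels independent of features, the resubstitution cost
        underestimates the true error: CV cost >= resubstitution cost in at
        least 90% of replicates."""
        rng = np.random.default_rng(2024)
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            X = rng.normal(size=(100, 3))
            y = np.where(rng.random(100) < 0.5, TUMOR, ASTROGLIOSIS)
            tree = fit_cart(X, y, CartParams(cv_folds=5, seed=rep))
            if tree.cv_cost >= tree.resubstitution_cost:
                wins += 1
        assert wins >= 0.9 * n_rep

    def test_node_p_values_populated(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 2))
        y = np.where(X[:, 0] > 0, TUMOR, ASTROGLIOSIS)
        tree = fit_cart(X, y, CartParams(cv_folds=2, seed=0))
        assert not tree.root.is_leaf
        assert 0.0 <= tree.root.left.p_value <= 1.0

    def test_direct_stop_limits_node_size(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 1))
        y = np.where(rng.random(100) < 0.5, TUMOR, ASTROGLIOSIS)
        tree = fit_cart(X, y, CartParams(min_node_fraction=0.5, cv_folds=2))

        def leaves(node):
            if node.is_leaf:
                return [node]
            return leaves(node.left) + leaves(node.right)

        # any split node must have held at least half the data
        def check(node):
            if not node.is_leaf:
                assert node.n >= 50
                check(node.left)
                check(node.right)

        check(tree.root)

    def test_json_roundtrip_preserves_predictions(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 1] > 0.2, TUMOR, ASTROGLIOSIS)
        tree = fit_cart(X, y, CartParams(cv_folds=3, seed=5))
        back = CartTree.from_json(tree.to_json())
        X_test = rng.normal(size=(30, 3))
        assert np.array_equal(
            predict_cart(tree, X_test), predict_cart(back, X_test)
        )


class TestPredictCart:
    def test_single_leaf_always_same_class(self):
        tree = fit_cart(np.array([[1.0], [2.0]]), np.array([TUMOR, TUMOR]), CartParams(cv_folds=2))
        assert list(predict_cart(tree, np.array([[0.0], [100.0]]))) == [TUMOR, TUMOR]

    def test_left_branch_on_boundary(self):
        X = np.array([[1.0], [2.0], [4.0], [5.0]])
        y = np.array([ASTROGLIOSIS, ASTROGLIOSIS, TUMOR, TUMOR])
        tree = fit_cart(X, y, CartParams(cv_folds=2))
        assert predict_cart(tree, np.array([[2.0]]))[0] == ASTROGLIOSIS
        assert predict_cart(tree, np.array([[3.0]]))[0] == ASTROGLIOSIS  # <= threshold goes left

    def test_invariant_to_irrelevant_features(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.where(X[:, 0] > 0, TUMOR, ASTROGLIOSIS)
        df = pd.DataFrame(X, columns=["a", "b"])
        tree = fit_cart(df[["a"]], y, CartParams(cv_folds=2))
        row = {"a": 1.0, "b": -5.0}
        row2 = {"a": 1.0, "b": 99.0}
        assert predict_cart(tree, row) == predict_cart(tree, row2)

    def test_missing_split_feature_rejected(self):
        X = np.array([[1.0], [2.0], [4.0], [5.0]])
        y = np.array([ASTROGLIOSIS, ASTROGLIOSIS, TUMOR, TUMOR])
        tree = fit_cart(pd.DataFrame(X, columns=["f"]), y, CartParams(cv_folds=2))
        with pytest.raises(KeyError, match="missing split feature"):
            predict_cart(tree, {"g": 1.0})


class TestSklearnEstimators:
    def test_cart_classifier_fit_predict(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 2)), columns=["u", "v"])
        y = np.where(X["u"] > 0, TUMOR, ASTROGLIOSIS)
        clf = CartClassifier(cv_folds=4, random_state=0).fit(X, y)
        assert set(clf.classes_) == {TUMOR, ASTROGLIOSIS}
        assert clf.resubstitution_cost_ <= clf.cv_cost_ + 0.15
        assert (clf.predict(X) == y).mean() > 0.9

    def test_get_set_params_roundtrip(self):
        clf = CartClassifier(min_node_fraction=0.1)
        params = clf.get_params()
        assert params["min_node_fraction"] == 0.1
        clf.set_params(max_depth=3)
        assert clf.max_depth == 3

    def test_threshold_classifier_youden_fit(self, rng):
        scores = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(2, 0.2, 100)])
        y = np.array([ASTROGLIOSIS] * 100 + [TUMOR] * 100)
        X = pd.DataFrame({"f": scores})
        clf = ThresholdClassifier(feature="f", cutoff=None).fit(X, y)
        assert 0.5 < clf.cutoff_ < 1.7
        assert (clf.predict(X) == y).all()

    def test_published_tree_classifier_matches_function(self, rng):
        X = pd.DataFrame(
            {"tbr_plexus_60": rng.uniform(0, 3, 50), "module": rng.uniform(0, 4, 50)}
        )
        preds = PublishedTreeClassifier().fit(X).predict(X)
        expected = [
            published_tree_classify(t, m) for t, m in zip(X["tbr_plexus_60"], X["module"])
        ]
        assert list(preds) == expected

    def test_dual_plexus_classifier_in_sklearn_pipeline(self, rng):
        from sklearn.pipeline import Pipeline

        X = pd.DataFrame(
            {"tbr_plexus_10": rng.uniform(0, 2, 20), "tbr_plexus_60": rng.uniform(0, 2, 20)}
        )
        pipe = Pipeline([("rule", DualPlexusClassifier())])
        preds = pipe.fit(X).predict(X)
        assert set(preds) <= {TUMOR, ASTROGLIOSIS}
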