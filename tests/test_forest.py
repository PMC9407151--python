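"""Forest training, prediction, learning curves and ROC."""

from __future__ import annotations

import numpy as np
import pytest

import frfseg
from frfseg.errors import ConfigurationError, EvaluationError, TrainingError
from frfseg.forest import _fit_forest

from conftest import make_stack


def brute_force_best_split(X: np.ndarray, y: np.ndarray, n_classes: int):
    """Exhaustive enumeration of every (feature, midpoint-threshold) split.

    Minimizes the weighted Gini impurity; ties resolve to the lowest
    feature index, then the lowest threshold — independent oracle for the
    tree builder's split search.
    """
    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.bincount(labels, minlength=n_classes) / len(labels)
        return 1.0 - (p**2).sum()

    best = None  # (impurity, feature, threshold)
    n = len(y)
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            go_left = X[:, f] <= thr
            imp = (go_left.sum() * gini(y[go_left]) + (~go_left).sum() * gini(y[~go_left])) / n
            if best is None or imp < best[0] - 1e-12:
                best = (imp, f, thr)
    return best


def probability_map_from_planes(p1: np.ndarray) -> frfseg.ProbabilityMap:
    """Two-class map with the given positive plane (complement fills class 0)."""
    return frfseg.ProbabilityMap(
        planes=np.stack([1.0 - p1, p1]), class_names=["neg", "pos"]
    )


class TestTrain:
    def test_separable_fixture_reaches_precision_one(self, separable):
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=50, seed=0)
        metrics = frfseg.evaluate(model, stack, labels)
        assert metrics["micro_precision"] == 1.0
        assert metrics["micro_recall"] == 1.0

    def test_single_label_per_class_is_memorized(self):
        stack = make_stack(np.arange(16.0).reshape(4, 4))
        labels = frfseg.LabelSet(
            classes=["a", "b"],
            coords={"a": np.array([[0, 0]]), "b": np.array([[3, 3]])},
        )
        model = frfseg.train(stack, labels, n_trees=20, seed=0)
        proba = model.predict_proba_samples(stack.sample(np.array([[0, 0], [3, 3]])))
        assert proba.argmax(axis=1).tolist() == [0, 1]

    @pytest.mark.parametrize("seed", [0, 1, 7, 23, 101])
    def test_root_split_matches_exhaustive_enumeration(self, seed):
        """Single tree with all features: root split equals the brute-force
        optimum on the tree's bootstrap resample (<=10 samples, <=3 features)."""
        rng = np.random.default_rng(seed)
        n, f = 8, 3
        X = np.round(rng.random((n, f)), 2)
        y = np.array([0, 1] * (n // 2))
        model = _fit_forest(X, y, ["a", "b"], n_trees=1,
                            features_per_split=f, seed=seed)
        boot = np.random.default_rng(model.tree_seeds[0]).integers(0, n, size=n)
        Xb, yb = X[boot], y[boot]
        if len(np.unique(yb)) < 2:
            pytest.skip("bootstrap drew a single class")
        oracle = brute_force_best_split(Xb, yb, 2)
        tree = model.trees[0]
        assert tree.feature[0] == oracle[1]
        assert tree.threshold[0] == pytest.approx(oracle[2])

    def test_fewer_than_two_classes_rejected(self, separable):
        stack, _ = separable
        labels = frfseg.LabelSet(classes=["only"], coords={"only": np.array([[0, 0]])})
        with pytest.raises(TrainingError):
            frfseg.train(stack, labels)

    def test_empty_class_rejected(self, separable):
        stack, _ = separable
        labels = frfseg.LabelSet(
            classes=["a", "b"],
            coords={"a": np.array([[0, 0]]), "b": np.empty((0, 2), dtype=np.intp)},
        )
        with pytest.raises(TrainingError):
            frfseg.train(stack, labels)

    def test_model_json_roundtrip_predicts_identically(self, separable):
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=10, seed=4)
        back = frfseg.FRFModel.from_json(model.to_json())
        X = stack.flat()
        np.testing.assert_array_equal(
            model.predict_proba_samples(X), back.predict_proba_samples(X)
        )

    def test_sklearn_forest_agrees_on_separable_fixture(self, separable):
        """Independent implementation cross-check: sklearn's forest also
        classifies every labeled pixel correctly on the separable fixture."""
        from sklearn.ensemble import RandomForestClassifier

        stack, labels = separable
        coords, y = labels.stacked()
        X = stack.sample(coords)
        skl = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        ours = frfseg.train(stack, labels, n_trees=50, seed=0)
        pred_ours = ours.predict_proba_samples(X).argmax(axis=1)
        np.testing.assert_array_equal(skl.predict(X), y)
        np.testing.assert_array_equal(pred_ours, y)


class TestPredict:
    def test_labeled_pixels_reproduce_training_classes(self, separable):
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=30, seed=2)
        class_map, _ = frfseg.predict(model, stack)
        for k, name in enumerate(labels.classes):
            c = labels.coords[name]
            assert (class_map[c[:, 0], c[:, 1]] == k).all()

    def test_single_tree_probabilities_are_leaf_frequencies(self, separable):
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=1, seed=3)
        _, prob = frfseg.predict(model, stack)
        # trees grow to purity on distinct-valued features: leaves are pure
        assert np.isin(prob.planes, [0.0, 1.0]).all()

    def test_ensemble_equals_mean_of_single_tree_maps(self, separable):
        """K-tree probabilities == arithmetic mean of the K single-tree maps
        built from the corresponding sub-seeds."""
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=3, seed=9)
        singles = [
            frfseg.train(stack, labels, n_trees=1, seed=9, tree_seeds=[ts])
            for ts in model.tree_seeds
        ]
        _, prob = frfseg.predict(model, stack)
        single_planes = [frfseg.predict(m, stack)[1].planes for m in singles]
        np.testing.assert_allclose(prob.planes, np.mean(single_planes, axis=0), atol=1e-12)

    def test_probabilities_sum_to_one_per_pixel(self, separable):
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=7, seed=5)
        _, prob = frfseg.predict(model, stack)
        np.testing.assert_allclose(prob.planes.sum(axis=0), 1.0, atol=1e-12)

    def test_seed_determinism_of_model_and_maps(self, separable):
        stack, labels = separable
        a = frfseg.train(stack, labels, n_trees=10, seed=11)
        b = frfseg.train(stack, labels, n_trees=10, seed=11)
        assert a.to_json() == b.to_json()
        np.testing.assert_array_equal(
            frfseg.predict(a, stack)[1].planes, frfseg.predict(b, stack)[1].planes
        )

    def test_feature_count_mismatch_rejected(self, separable):
        stack, labels = separable
        model = frfseg.train(stack, labels, n_trees=2, seed=0)
        wrong = make_stack(np.zeros((8, 8)), np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ConfigurationError):
            frfseg.predict(model, wrong)


class TestLearningCurve:
    def test_precision_reaches_one_and_stays(self, separable):
        stack, labels = separable
        total = labels.n_labels
        curve = frfseg.learning_curve(
            stack, labels, schedule=[4, 10, 25, 50, total], n_trees=30, seed=1
        )
        assert curve.instances == sorted(curve.instances)
        reached = [p == 1.0 for p in curve.precision]
        assert any(reached)
        first = reached.index(True)
        assert all(reached[first:])

    def test_full_schedule_point_matches_train_and_evaluate(self, separable):
        stack, labels = separable
        total = labels.n_labels
        curve = frfseg.learning_curve(stack, labels, schedule=[total], n_trees=20, seed=6)
        model = frfseg.train(stack, labels, n_trees=20, seed=6)
        metrics = frfseg.evaluate(model, stack, labels)
        assert curve.precision[-1] == pytest.approx(metrics["micro_precision"])
        assert curve.recall[-1] == pytest.approx(metrics["micro_recall"])

    def test_schedule_of_one_flags_unseen_class(self, separable):
        stack, labels = separable
        curve = frfseg.learning_curve(stack, labels, schedule=[1], n_trees=5, seed=0)
        assert len(curve.unseen_classes[0]) == 1
        seen = (set(labels.classes) - set(curve.unseen_classes[0])).pop()
        unseen = curve.unseen_classes[0][0]
        assert curve.per_class[seen]["precision"][0] == 1.0
        assert curve.per_class[unseen]["precision"][0] == 0.0

    def test_empty_schedule_rejected(self, separable):
        stack, labels = separable
        with pytest.raises(ConfigurationError):
            frfseg.learning_curve(stack, labels, schedule=[])

    def test_schedule_beyond_labels_rejected(self, separable):
        stack, labels = separable
        with pytest.raises(ConfigurationError):
            frfseg.learning_curve(stack, labels, schedule=[labels.n_labels + 1])


class TestROC:
    def _truth(self):
        return frfseg.LabelSet(
            classes=["neg", "pos"],
            coords={
                "neg": np.array([[0, 0], [0, 1]]),
                "pos": np.array([[1, 0], [1, 1]]),
            },
        )

    def test_perfect_separation_gives_ideal_curve(self):
        p1 = np.array([[0.0, 0.0], [1.0, 1.0]])
        curve = frfseg.roc(probability_map_from_planes(p1), self._truth(), "pos")
        assert curve.auc == pytest.approx(1.0)
        # the ideal classifier's curve passes through (0, 1)
        assert any(fpr == 0.0 and tpr == 1.0 for fpr, tpr in curve.roc_points)

    def test_constant_probabilities_give_chance_auc(self):
        p1 = np.full((2, 2), 0.5)
        curve = frfseg.roc(probability_map_from_planes(p1), self._truth(), "pos")
        assert curve.auc == pytest.approx(0.5)

    def test_four_pixel_threshold_enumeration(self):
        # positives score (0.9, 0.8), negatives (0.4, 0.1): every threshold
        # in (0.4, 0.8] separates perfectly -> AUC 1 by hand enumeration
        p1 = np.array([[0.4, 0.1], [0.9, 0.8]])
        curve = frfseg.roc(probability_map_from_planes(p1), self._truth(), "pos")
        assert curve.auc == pytest.approx(1.0)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        p1 = rng.random((4, 4))
        truth = frfseg.LabelSet(
            classes=["neg", "pos"],
            coords={
                "neg": np.column_stack([np.zeros(4, int), np.arange(4)]),
                "pos": np.column_stack([np.ones(4, int), np.arange(4)]),
            },
        )
        curve = frfseg.roc(probability_map_from_planes(p1), truth, "pos")
        pts = curve.roc_points
        np.testing.assert_allclose(pts[0], [0.0, 0.0])
        np.testing.assert_allclose(pts[-1], [1.0, 1.0])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_one_sided_truth_rejected(self):
        truth = frfseg.LabelSet(classes=["neg", "pos"],
                                coords={"neg": np.empty((0, 2), dtype=np.intp),
                                        "pos": np.array([[0, 0]])})
        p1 = np.zeros((2, 2))
        with pytest.raises(EvaluationError):
            frfseg.roc(probability_map_from_planes(p1), truth, "pos")
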