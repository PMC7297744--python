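"""Reference assembly, CART training/pruning, fuzzy prediction, metrics."""

import json

import numpy as np
import pandas as pd
import pytest

import shrubscan as ss
from shrubscan.classify import (LabeledFeatureSet, confusion_matrix, evaluate,
                                predict_fuzzy, repeated_validation,
                                stratified_split, train_tree)
from shrubscan.pointcloud import Layer, ReferenceRecord


def labelled_set(X, y, k=None, names=None):
    k = k or int(np.max(y)) + 1
    schema = tuple(f"c{i}" for i in range(k))
    names = names or tuple(f"f{j}" for j in range(np.atleast_2d(X).shape[1]))
    return LabeledFeatureSet(np.atleast_2d(X), y, schema, names)


def separable_two_class(n=100, seed=0, gap=5.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x0 = np.where(y == 0, 0.0, gap) + rng.normal(0, 0.3, n)
    x1 = rng.normal(0, 1, n)
    return labelled_set(np.column_stack([x0, x1]), y)


class TestAssembleReference:
    def _featurized_cloud(self):
        # two tight clusters of shrub-layer points plus bare ground
        pts = []
        for cx in (2.0, 6.0):
            for k in range(10):
                pts.append([cx + 0.05 * k - 0.25, 5.0, 41.0 + 0.01 * k])
        pts += [[4.0, 1.0, 40.0]]
        arr = np.array(pts)
        n = arr.shape[0]
        cloud = ss.PointCloud(arr[:, 0], arr[:, 1], arr[:, 2],
                              np.ones(n, int), np.ones(n, int),
                              norm_z=np.r_[np.full(20, 1.0), 0.0])
        cloud = ss.assign_layers(cloud)
        feats = ss.compute_features(cloud)
        return cloud, feats

    def test_isolated_shrub_gets_all_and_only_its_points(self):
        cloud, feats = self._featurized_cloud()
        refs = [ReferenceRecord(1, 2.0, 5.0, 41.0, 0, 0.6)]
        lab = ss.assemble_reference(cloud, feats, refs, ("a", "b"))
        assert len(lab) == 10
        assert np.all(lab.labels == 0)

    def test_record_over_bare_ground_is_skipped_with_warning(self):
        cloud, feats = self._featurized_cloud()
        refs = [ReferenceRecord(1, 2.0, 5.0, 41.0, 0, 0.6),
                ReferenceRecord(2, 4.0, 1.0, 40.0, 1, 0.5)]
        with pytest.warns(UserWarning, match="reference 2"):
            lab = ss.assemble_reference(cloud, feats, refs, ("a", "b"))
        assert np.all(lab.labels == 0)

    def test_disputed_points_go_to_nearer_record(self):
        cloud, feats = self._featurized_cloud()
        # both records cover the first cluster (x in [1.75, 2.2])
        refs = [ReferenceRecord(1, 1.5, 5.0, 41.0, 0, 1.0),
                ReferenceRecord(2, 2.5, 5.0, 41.0, 1, 1.0)]
        lab = ss.assemble_reference(cloud, feats, refs, ("a", "b"))
        x = feats["x"].to_numpy()[:10]
        # strictly nearer record wins; an exact tie keeps the earlier record
        expected = np.where(np.abs(x - 1.5) <= np.abs(x - 2.5), 0, 1)
        np.testing.assert_array_equal(np.sort(lab.labels),
                                      np.sort(expected))


class TestStratifiedSplit:
    def test_ninety_ten_per_class(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 100)
        data = labelled_set(rng.normal(size=(200, 2)), y)
        train, test = stratified_split(data, 0.9, seed=0)
        for cls in (0, 1):
            assert np.sum(train.labels == cls) == 90
            assert np.sum(test.labels == cls) == 10

    def test_same_seed_identical_split(self):
        data = separable_two_class(seed=2)
        t1, v1 = stratified_split(data, 0.7, seed=5)
        t2, v2 = stratified_split(data, 0.7, seed=5)
        np.testing.assert_array_equal(t1.features, t2.features)
        np.testing.assert_array_equal(v1.labels, v2.labels)

    def test_singleton_class_errors_with_name(self):
        data = labelled_set(np.arange(4.0)[:, None], np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError, match="c1"):
            stratified_split(data, 0.9, seed=0)

    def test_full_train_fraction_returns_everything(self):
        data = separable_two_class()
        train, _ = stratified_split(data, 1.0, seed=0)
        assert len(train) == len(data)


class TestTrainTree:
    def test_separable_gap_yields_single_pure_split(self):
        data = separable_two_class(gap=10.0)
        model = train_tree(data, cp=0.001)
        assert model.n_leaves == 2
        assert np.mean(model.predict(data.features) == data.labels) == 1.0
        probs = model.predict_proba(data.features)
        assert np.all(np.max(probs, axis=1) == 1.0)

    def test_cp_one_gives_root_only_tree(self):
        data = separable_two_class(gap=10.0)
        model = train_tree(data, cp=1.0)
        assert model.n_leaves == 1

    def test_leaf_proportions(self):
        # one feature that cannot separate 7 A from 3 B in the right leaf
        X = np.r_[np.zeros(5), np.ones(10)][:, None]
        y = np.r_[np.full(5, 1), np.full(7, 0), np.full(3, 1)].astype(int)
        data = labelled_set(X, y)
        model = train_tree(data, cp=0.001)
        probs = model.predict_proba(np.array([[1.0]]))
        np.testing.assert_allclose(probs[0], [0.7, 0.3])

    def test_single_class_is_error(self):
        data = labelled_set(np.arange(10.0)[:, None], np.zeros(10, dtype=int),
                            k=2)
        with pytest.raises(ValueError, match="2 classes"):
            train_tree(data)

    def test_pruning_monotone_in_cp(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = ((X[:, 0] + 0.5 * rng.normal(size=200)) > 0).astype(int)
        data = labelled_set(X, y)
        leaves = [train_tree(data, cp=cp).n_leaves
                  for cp in (0.0, 0.001, 0.01, 0.1, 1.0)]
        assert all(a >= b for a, b in zip(leaves, leaves[1:]))

    def test_agrees_with_sklearn_on_separable_data(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        data = separable_two_class(gap=8.0, seed=9)
        model = train_tree(data, cp=0.001)
        clf = sklearn_tree.DecisionTreeClassifier(random_state=0)
        clf.fit(data.features, data.labels)
        np.testing.assert_array_equal(model.predict(data.features),
                                      clf.predict(data.features))


class TestPredictFuzzy:
    def test_probabilities_sum_to_one_and_match_argmax(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 3))
        y = (X[:, 0] > 0).astype(int) + 2 * (X[:, 1] > 0).astype(int)
        data = labelled_set(X, y)
        model = train_tree(data, cp=0.001)
        probs, labels = predict_fuzzy(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(labels, np.argmax(probs, axis=1))

    def test_matches_independent_json_traversal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        data = labelled_set(X, y)
        model = train_tree(data, cp=0.001)
        spec = json.loads(model.to_json())

        def walk(node, row):  # independently coded traversal
            while "feature" in node:
                node = node["left"] if row[node["feature"]] <= node["threshold"] \
                    else node["right"]
            c = np.asarray(node["counts"], dtype=float)
            return int(np.argmax(c / c.sum()))

        oracle = [walk(spec["tree"], row) for row in X]
        np.testing.assert_array_equal(model.predict(X), oracle)

    def test_json_round_trip(self):
        data = separable_two_class()
        model = train_tree(data)
        back = ss.FuzzyTreeModel.from_json(model.to_json())
        np.testing.assert_allclose(back.predict_proba(data.features),
                                   model.predict_proba(data.features))


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = evaluate(y, y, 3)
        assert rep.overall_accuracy == 1.0
        assert rep.kappa == 1.0
        np.testing.assert_allclose(rep.f1, 1.0)

    def test_hand_computed_kappa(self):
        # confusion matrix [[40, 10], [5, 45]]
        true = np.r_[np.zeros(50, int), np.ones(50, int)]
        pred = np.r_[np.zeros(40, int), np.ones(10, int),
                     np.zeros(5, int), np.ones(45, int)]
        m = confusion_matrix(pred, true, 2)
        np.testing.assert_array_equal(m, [[40, 10], [5, 45]])
        rep = evaluate(pred, true, 2)
        assert rep.overall_accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.70)

    def test_f1_is_harmonic_mean(self):
        # precision 0.8, recall 0.6 for the positive class:
        # TP = 12, FP = 3, FN = 8
        true = np.r_[np.ones(20, int), np.zeros(20, int)]
        pred = np.r_[np.ones(12, int), np.zeros(8, int),
                     np.ones(3, int), np.zeros(17, int)]
        rep = evaluate(pred, true, 2)
        assert rep.precision[1] == pytest.approx(0.8)
        assert rep.recall[1] == pytest.approx(0.6)
        assert rep.f1[1] == pytest.approx(2 * 0.8 * 0.6 / 1.4)
        assert rep.f1[1] == pytest.approx(0.6857, abs=1e-4)

    def test_matches_sklearn_metrics(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(6)
        true = rng.integers(0, 4, 300)
        pred = np.where(rng.uniform(size=300) < 0.7, true,
                        rng.integers(0, 4, 300))
        rep = evaluate(pred, true, 4)
        assert rep.overall_accuracy == pytest.approx(
            metrics.accuracy_score(true, pred))
        assert rep.kappa == pytest.approx(
            metrics.cohen_kappa_score(true, pred))
        p, r, f, _ = metrics.precision_recall_fscore_support(
            true, pred, labels=range(4), zero_division=np.nan)
        np.testing.assert_allclose(rep.precision, p, atol=1e-12)
        np.testing.assert_allclose(rep.recall, r, atol=1e-12)
        np.testing.assert_allclose(rep.f1, f, atol=1e-12)

    def test_kappa_bounded_by_accuracy(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            true = rng.integers(0, 3, 60)
            pred = rng.integers(0, 3, 60)
            rep = evaluate(pred, true, 3)
            assert 0.0 <= rep.overall_accuracy <= 1.0
            assert rep.kappa <= rep.overall_accuracy + 1e-12


class TestRepeatedValidation:
    def test_separable_data_scores_perfectly(self):
        data = separable_two_class(gap=10.0)
        summary = repeated_validation(data, 0.9, n_iter=10, base_seed=1)
        assert summary.oa_mean == 1.0
        assert summary.oa_sd == 0.0

    def test_fixed_seed_is_bit_identical(self):
        data = separable_two_class(gap=2.0, seed=8)
        s1 = repeated_validation(data, 0.7, n_iter=5, base_seed=3)
        s2 = repeated_validation(data, 0.7, n_iter=5, base_seed=3)
        assert s1.oa_mean == s2.oa_mean
        assert s1.kappa_sd == s2.kappa_sd
        np.testing.assert_array_equal(s1.f1_mean, s2.f1_mean)

    def test_single_iteration_equals_single_split(self):
        data = separable_two_class(gap=2.0, seed=8)
        s = repeated_validation(data, 0.9, n_iter=1, base_seed=11)
        train, test = stratified_split(data, 0.9, seed=11)
        model = train_tree(train)
        rep = evaluate(model.predict(test.features), test.labels, 2)
        assert s.oa_mean == rep.overall_accuracy
        assert s.oa_sd == 0.0


class TestClassWeights:
    def test_upweighting_minority_class_shifts_leaf_probabilities(self):
        # 90/10 imbalance inside an unsplittable leaf
        X = np.zeros((100, 1))
        y = np.r_[np.zeros(90, int), np.ones(10, int)]
        data = labelled_set(X, y)
        plain = train_tree(data, cp=0.001)
        np.testing.assert_allclose(
            plain.predict_proba(np.zeros((1, 1)))[0], [0.9, 0.1])
        weighted = train_tree(data, cp=0.001,
                              class_weight=np.array([1.0, 9.0]))
        np.testing.assert_allclose(
            weighted.predict_proba(np.zeros((1, 1)))[0], [0.5, 0.5])

    def test_uniform_weights_match_default(self):
        data = separable_two_class(gap=2.0, seed=10)
        a = train_tree(data, cp=0.001)
        b = train_tree(data, cp=0.001, class_weight=np.ones(2))
        assert a.to_json() == b.to_json()

    def test_invalid_weights_rejected(self):
        data = separable_two_class()
        with pytest.raises(ValueError, match="class_weight"):
            train_tree(data, class_weight=np.array([1.0, 0.0]))
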