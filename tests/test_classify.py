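"""K-NN and decision-tree graders against brute-force and sklearn oracles."""

import numpy as np
import pytest

import kneegrade as kg
from kneegrade.classify import (
    LabeledFeatureSet,
    stratified_two_fold_indices,
    tree_predict_many,
    knn_predict_many,
    decision_tree_fit,
    tree_predict,
)
from kneegrade.exceptions import InvalidArgumentError


def make_set(features, labels):
    return LabeledFeatureSet(features=np.asarray(features, float), labels=labels)


def pad7(rows):
    """Embed low-dimensional toy points into the 7-feature space."""
    rows = np.asarray(rows, float)
    out = np.zeros((rows.shape[0], 7))
    out[:, : rows.shape[1]] = rows
    return out


def five_clusters(rng, n_train, n_test, sd_frac=0.1):
    """Five well-separated 7-D Gaussian clusters, sd = sd_frac x separation."""
    centers = rng.normal(0, 1, size=(5, 7))
    # enforce a known minimum separation
    centers *= 10.0 / np.linalg.norm(centers[0] - centers[1])
    sep = min(
        np.linalg.norm(centers[i] - centers[j]) for i in range(5) for j in range(i + 1, 5)
    )

    def draw(n):
        X, y = [], []
        for g in range(5):
            X.append(rng.normal(centers[g], sd_frac * sep, size=(n // 5, 7)))
            y.extend([g] * (n // 5))
        return np.vstack(X), np.array(y)

    return draw(n_train), draw(n_test)


def brute_force_knn(train_X, train_y, query, k, mean=None, scale=None):
    """Independent exhaustive neighbor search with the documented tie-breaks."""
    X, q = np.asarray(train_X, float), np.asarray(query, float)
    if mean is not None:
        X = (X - mean) / scale
        q = (q - mean) / scale
    d = np.array([np.sqrt(((row - q) ** 2).sum()) for row in X])
    nearest = sorted(range(len(d)), key=lambda i: d[i])[:k]
    candidates = {}
    for i in nearest:
        lab = int(train_y[i])
        votes, sums = candidates.get(lab, (0, 0.0))
        candidates[lab] = (votes + 1, sums + d[i])
    return min(candidates, key=lambda lab: (-candidates[lab][0], candidates[lab][1], lab))


class TestKnn:
    def test_single_training_sample_predicts_its_label(self, rng):
        ds = make_set(pad7([[1.0, 2.0]]), [kg.KLGrade.MODERATE])
        model = kg.knn_fit(ds, k=1)
        for _ in range(5):
            assert kg.knn_predict(model, rng.normal(size=7)) == kg.KLGrade.MODERATE

    def test_exact_training_point_k1(self, rng):
        X = rng.normal(size=(20, 7))
        y = rng.integers(0, 5, size=20)
        model = kg.knn_fit(make_set(X, y), k=1)
        for i in (0, 7, 19):
            assert int(kg.knn_predict(model, X[i])) == y[i]

    def test_fit_deterministic(self, rng):
        X = rng.normal(size=(30, 7))
        y = rng.integers(0, 5, size=30)
        probes = rng.normal(size=(10, 7))
        p1 = knn_predict_many(kg.knn_fit(make_set(X, y), k=3), probes)
        p2 = knn_predict_many(kg.knn_fit(make_set(X, y), k=3), probes)
        assert np.array_equal(p1, p2)

    def test_equidistant_tie_breaks_to_lower_ordinal(self):
        ds = make_set(pad7([[-1.0], [1.0]]), [kg.KLGrade.SEVERE, kg.KLGrade.MILD])
        model = kg.knn_fit(ds, k=2, standardize=False)
        assert kg.knn_predict(model, np.zeros(7)) == kg.KLGrade.MILD

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(200, 7)) * np.array([1, 0.5, 2, 1, 3, 0.1, 1])
        y = rng.integers(0, 5, size=200)
        model = kg.knn_fit(make_set(X, y), k=5)
        for q in rng.normal(size=(40, 7)):
            expected = brute_force_knn(
                X, y, q, k=5, mean=model.feature_mean, scale=model.feature_scale
            )
            assert int(kg.knn_predict(model, q)) == expected

    def test_matches_sklearn_on_tie_free_data(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        (Xtr, ytr), (Xte, _) = five_clusters(rng, 100, 50)
        model = kg.knn_fit(make_set(Xtr, ytr), k=3, standardize=False)
        ref = KNeighborsClassifier(n_neighbors=3).fit(Xtr, ytr)
        assert np.array_equal(knn_predict_many(model, Xte), ref.predict(Xte))

    def test_well_separated_clusters_high_accuracy(self, rng):
        (Xtr, ytr), (Xte, yte) = five_clusters(rng, 100, 100)
        model = kg.knn_fit(make_set(Xtr, ytr), k=3)
        acc = (knn_predict_many(model, Xte) == yte).mean()
        assert acc >= 0.95

    def test_invalid_k_rejected(self, rng):
        ds = make_set(rng.normal(size=(5, 7)), rng.integers(0, 5, size=5))
        with pytest.raises(InvalidArgumentError):
            kg.knn_fit(ds, k=6)
        with pytest.raises(InvalidArgumentError):
            kg.knn_fit(ds, k=0)

    def test_nan_features_rejected(self):
        X = np.zeros((3, 7))
        X[1, 2] = np.nan
        with pytest.raises(InvalidArgumentError):
            make_set(X, [0, 1, 2])


class TestDecisionTree:
    def test_one_threshold_data_gives_depth_one_perfect_tree(self):
        X = pad7([[0.0], [1.0], [10.0], [11.0]])
        ds = make_set(X, [0, 0, 4, 4])
        model = decision_tree_fit(ds, max_depth=8)
        assert model.root.feature == 0
        assert model.root.left.label == 0 and model.root.right.label == 4
        assert np.array_equal(tree_predict_many(model, X), [0, 0, 4, 4])

    def test_pure_data_single_leaf(self):
        ds = make_set(np.random.default_rng(0).normal(size=(10, 7)), [2] * 10)
        model = decision_tree_fit(ds)
        assert model.root.label == 2
        assert model.root.feature is None

    def test_beats_majority_baseline_on_training_data(self, rng):
        X = rng.normal(size=(50, 7))
        y = (X[:, 3] > 0).astype(int) * 2  # depends on a feature: learnable
        y[rng.integers(0, 50, size=5)] = 4  # plus some noise
        ds = make_set(X, y)
        model = decision_tree_fit(ds, max_depth=6)
        acc = (tree_predict_many(model, X) == y).mean()
        baseline = max(np.bincount(y)) / len(y)
        assert acc >= baseline

    def test_invalid_depth_rejected(self, rng):
        ds = make_set(rng.normal(size=(4, 7)), [0, 1, 2, 3])
        with pytest.raises(InvalidArgumentError):
            decision_tree_fit(ds, max_depth=0)

    def test_tie_breaks_lowest_feature_index(self):
        # features 0 and 1 are identical, both split perfectly
        X = pad7([[0.0, 0.0], [1.0, 1.0], [0.2, 0.2], [0.8, 0.8]])
        ds = make_set(X, [0, 1, 0, 1])
        model = decision_tree_fit(ds, max_depth=1)
        assert model.root.feature == 0


class TestTwoFoldCV:
    def test_one_hot_features_perfectly_separable(self):
        X = np.eye(5)[np.repeat(np.arange(5), 4)] @ np.eye(5, 7)
        y = np.repeat(np.arange(5), 4)
        res = kg.two_fold_cv(make_set(X, y), classifier="knn", seed=0, k=1)
        assert res.accuracy == 1.0
        assert np.array_equal(res.confusion, np.diag(np.bincount(y)))

    def test_same_seed_reproduces_confusion(self, rng):
        (Xtr, ytr), _ = five_clusters(rng, 100, 10)
        ds = make_set(Xtr, ytr)
        a = kg.two_fold_cv(ds, seed=42)
        b = kg.two_fold_cv(ds, seed=42)
        assert np.array_equal(a.confusion, b.confusion)

    def test_knn_beats_tree_on_separated_clusters(self, rng):
        (Xtr, ytr), _ = five_clusters(rng, 200, 10)
        ds = make_set(Xtr, ytr)
        knn = kg.two_fold_cv(ds, classifier="knn", seed=1, k=3)
        tree = kg.two_fold_cv(ds, classifier="tree", seed=1, max_depth=8)
        assert knn.accuracy >= 0.95
        assert knn.accuracy >= tree.accuracy

    def test_confusion_margins_match_counts(self, rng):
        (Xtr, ytr), _ = five_clusters(rng, 100, 10)
        res = kg.two_fold_cv(make_set(Xtr, ytr), seed=5)
        cm = res.confusion
        assert cm.sum() == len(ytr)
        assert np.array_equal(cm.sum(axis=0), np.bincount(ytr, minlength=5))
        assert np.array_equal(
            cm.sum(axis=1), np.bincount(res.predictions, minlength=5)
        )

    def test_small_class_rejected(self):
        X = np.zeros((6, 7))
        y = [0, 0, 1, 1, 2, 3]  # classes 2 and 3 have one sample
        with pytest.raises(InvalidArgumentError):
            stratified_two_fold_indices(np.array(y), seed=0)

    def test_stratified_split_halves_every_class(self, rng):
        labels = np.repeat(np.arange(5), 10)
        a, b = stratified_two_fold_indices(labels, seed=3)
        assert len(np.intersect1d(a, b)) == 0
        assert len(a) + len(b) == 50
        for g in range(5):
            assert np.sum(labels[a] == g) == 5
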