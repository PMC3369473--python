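import json

import numpy as np
import pytest

from tonguelab.classify import (
    AdaBoostModel,
    DegenerateTrainingError,
    LabeledSample,
    load_model,
    predict,
    predict_adaboost,
    predict_mlp,
    predict_svm,
    save_model,
    stack_dataset,
    train_adaboost,
    train_mlp,
    train_svm,
)
from tonguelab.classify.mlp import _softmax
from tonguelab.classify.svm import poly_kernel
from tonguelab.classify.tree import DecisionTree, fit_tree


class TestLabeledSample:
    def test_label_validation(self):
        with pytest.raises(ValueError):
            LabeledSample(x=[0.0], y=0)

    def test_stacking(self):
        data = [LabeledSample([0.1, 0.2], 1), LabeledSample([0.3, 0.4], -1)]
        X, y = stack_dataset(data)
        assert X.shape == (2, 2)
        assert list(y) == [1, -1]


class TestWeakTree:
    def test_stump_separates_threshold_data(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, -1, 1, 1])
        tree = fit_tree(X, y, np.full(4, 0.25), depth=1)
        assert list(tree.predict(X)) == list(y)

    def test_weighting_drives_split(self):
        # same points, but weight concentrates on a conflicting pair
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, -1, -1, -1])
        w = np.array([0.7, 0.1, 0.1, 0.1])
        tree = fit_tree(X, y, w, depth=1)
        assert tree.predict(np.array([[0.0]]))[0] == 1

    def test_json_roundtrip(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 0.5]])
        y = np.array([-1, 1, -1, 1])
        tree = fit_tree(X, y, np.full(4, 0.25), depth=2)
        clone = DecisionTree.from_dict(
            json.loads(json.dumps(tree.to_dict())))
        assert list(clone.predict(X)) == list(tree.predict(X))


class TestAdaBoost:
    def test_initial_distribution_uniform(self, blobs_2d):
        X, y = blobs_2d
        model = train_adaboost(X, y, T=3)
        assert np.allclose(model.weight_history[0], 1.0 / len(y))

    def test_alpha_formula(self):
        # eps = 0.1 -> alpha = 0.5 * ln 9
        eps = 0.1
        assert 0.5 * np.log((1 - eps) / eps) == pytest.approx(
            1.0986, abs=1e-4)

    def test_distributions_normalized_each_round(self, blobs_2d, rng):
        X, y = blobs_2d
        X = X + rng.normal(0, 1.2, X.shape)  # make it take several rounds
        model = train_adaboost(X, y, T=10)
        for D in model.weight_history:
            assert np.sum(D) == pytest.approx(1.0, abs=1e-12)

    def test_all_alphas_positive(self, blobs_2d):
        X, y = blobs_2d
        model = train_adaboost(X, y, T=10)
        assert all(alpha > 0 for _, alpha in model.rounds)

    def test_training_error_bounded_by_z_product(self, rng):
        X = rng.random((60, 4))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=60) > 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        model = train_adaboost(X, y, T=20)
        err = np.mean(predict_adaboost(model, X) != y)
        assert err <= np.prod(model.zs) + 1e-12

    def test_separable_reaches_zero_error(self, blobs_2d):
        X, y = blobs_2d
        model = train_adaboost(X, y, T=10)
        assert np.mean(predict_adaboost(model, X) != y) == 0.0
        assert len(model.rounds) <= 10

    def test_single_round_prediction_is_weak_label(self, blobs_2d):
        X, y = blobs_2d
        model = train_adaboost(X, y, T=5)
        single = AdaBoostModel(rounds=model.rounds[:1], T=1, depth=1,
                               n_features=X.shape[1])
        tree, _ = model.rounds[0]
        assert np.array_equal(
            predict_adaboost(single, X), tree.predict(X))

    def test_weighted_majority_of_two_rounds(self):
        X = np.array([[0.0, 0.0]])
        t_pos = fit_tree(np.array([[0.0], [1.0]]), np.array([1, 1]),
                         np.array([0.5, 0.5]), depth=1)
        t_neg = fit_tree(np.array([[0.0], [1.0]]), np.array([-1, -1]),
                         np.array([0.5, 0.5]), depth=1)
        model = AdaBoostModel(rounds=[(t_pos, 1.0), (t_neg, 0.4)],
                              T=2, depth=1, n_features=2)
        assert predict_adaboost(model, X)[0] == 1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_adaboost(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_feature_length_mismatch(self, blobs_2d):
        X, y = blobs_2d
        model = train_adaboost(X, y, T=2)
        with pytest.raises(ValueError):
            predict_adaboost(model, np.zeros((1, 5)))

    def test_determinism(self, blobs_2d):
        X, y = blobs_2d
        a = train_adaboost(X, y, T=10, seed=0)
        b = train_adaboost(X, y, T=10, seed=0)
        assert [alpha for _, alpha in a.rounds] == \
            [alpha for _, alpha in b.rounds]


class TestSvm:
    def test_two_point_bisector(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        y = np.array([-1, 1])
        model = train_svm(X, y, degree=1, standardize=False)
        mid = model.decision_function(np.array([[1.0, 1.0]]))[0]
        assert abs(mid) <= model.tol
        assert predict_svm(model, X).tolist() == [-1, 1]

    def test_xor_degree2(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        model = train_svm(X, y, C=10.0, degree=2, standardize=False)
        assert predict_svm(model, X).tolist() == list(y)

    def test_dual_equality_constraint(self, blobs_2d):
        X, y = blobs_2d
        model = train_svm(X, y, degree=1)
        assert abs(np.sum(model.y * model.alpha)) < model.tol

    def test_box_constraint(self, blobs_2d):
        X, y = blobs_2d
        model = train_svm(X, y, C=1.0, degree=1)
        assert np.all(model.alpha >= -1e-12)
        assert np.all(model.alpha <= model.C + 1e-12)

    def test_decision_matches_literal_formula(self, blobs_2d):
        X, y = blobs_2d
        model = train_svm(X, y, degree=2)
        Xs = model.standardizer.transform(X)
        manual = np.array([
            sum(model.y[i] * model.alpha[i]
                * (float(model.X[i] @ x) + model.coef) ** model.degree
                for i in range(len(model.y))) + model.b
            for x in Xs
        ])
        assert np.allclose(manual, model.decision_function(X), atol=1e-9)

    def test_determinism(self, blobs_2d):
        X, y = blobs_2d
        a = train_svm(X, y, seed=3)
        b = train_svm(X, y, seed=3)
        assert np.array_equal(a.alpha, b.alpha) and a.b == b.b

    def test_positive_decision_label(self, blobs_2d):
        X, y = blobs_2d
        model = train_svm(X, y)
        scores = model.decision_function(X)
        labels = predict_svm(model, X)
        assert np.all(labels[scores > 0] == 1)
        assert np.all(labels[scores < 0] == -1)


class TestMlp:
    def test_softmax_normalized(self, rng):
        z = rng.normal(size=(50, 2)) * 10
        p = _softmax(z)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_blobs_high_accuracy(self, blobs_2d):
        X, y = blobs_2d
        model = train_mlp(X, y, epochs=500, seed=0)
        acc = np.mean(predict_mlp(model, X) == y)
        assert acc >= 0.95

    def test_seeded_determinism(self, blobs_2d):
        X, y = blobs_2d
        a = train_mlp(X, y, epochs=50, seed=11)
        b = train_mlp(X, y, epochs=50, seed=11)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_probability_argmax_prediction(self, blobs_2d):
        X, y = blobs_2d
        model = train_mlp(X, y, epochs=100, seed=0)
        probs = model.forward(X)
        manual = np.where(probs[:, 0] >= probs[:, 1], 1, -1)
        assert np.array_equal(manual, predict_mlp(model, X))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_mlp(np.zeros((4, 2)), -np.ones(4, dtype=int))


class TestSerialization:
    @pytest.mark.parametrize("trainer,predictor", [
        (lambda X, y: train_adaboost(X, y, T=5), predict_adaboost),
        (lambda X, y: train_svm(X, y, degree=2), predict_svm),
        (lambda X, y: train_mlp(X, y, epochs=50), predict_mlp),
    ])
    def test_json_roundtrip(self, tmp_path, blobs_2d, trainer, predictor):
        X, y = blobs_2d
        model = trainer(X, y)
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        assert np.array_equal(predictor(clone, X), predictor(model, X))
        assert np.array_equal(predict(clone, X), predictor(model, X))


def test_poly_kernel_matches_definition(rng):
    A = rng.normal(size=(3, 4))
    B = rng.normal(size=(2, 4))
    K = poly_kernel(A, B, degree=3, coef=2.0)
    for i in range(3):
        for j in range(2):
            assert K[i, j] == pytest.approx(
                (float(A[i] @ B[j]) + 2.0) ** 3, rel=1e-12)
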