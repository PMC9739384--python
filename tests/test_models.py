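"""Gaussian naive Bayes against the closed-form density and oracles."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.naive_bayes import GaussianNB as SkGaussianNB

from imuquat.classifiers import (
    ClassifierSpec,
    GaussianNaiveBayes,
    default_specs,
    gnb_fit,
    gnb_predict,
    knn_k,
    train_classifier,
)
from imuquat.exceptions import ConfigurationError, InvalidInputError


TOY_X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0], [7.0, 8.0], [8.0, 7.0], [9.0, 9.0]])
TOY_Y = np.array(["a", "a", "a", "b", "b", "b"])


class TestFit:
    def test_two_point_classes(self):
        model = gnb_fit(np.array([[0.0], [0.0], [1.0], [1.0]]), np.array(["x", "x", "y", "y"]))
        np.testing.assert_allclose(model.priors_, [0.5, 0.5])
        np.testing.assert_allclose(model.means_, [[0.0], [1.0]])

    def test_moments_match_hand_computation(self):
        model = gnb_fit(TOY_X, TOY_Y)
        np.testing.assert_allclose(model.means_[0], [2.0, 2.0])
        np.testing.assert_allclose(model.means_[1], [8.0, 8.0])
        # population variance of {1,2,3} is 2/3
        np.testing.assert_allclose(model.variances_[0], [2 / 3, 2 / 3])
        np.testing.assert_allclose(model.variances_[1], [2 / 3, 2 / 3])
        assert abs(model.priors_.sum() - 1.0) < 1e-9

    def test_duplicating_rows_leaves_model_unchanged(self):
        base = gnb_fit(TOY_X, TOY_Y)
        doubled = gnb_fit(np.vstack([TOY_X, TOY_X]), np.concatenate([TOY_Y, TOY_Y]))
        np.testing.assert_allclose(base.means_, doubled.means_)
        np.testing.assert_allclose(base.variances_, doubled.variances_)
        np.testing.assert_allclose(base.priors_, doubled.priors_)

    def test_constant_feature_gets_floored_variance(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 5.0], [0.0, 6.0]])
        model = gnb_fit(X, np.array(["a", "a", "b", "b"]))
        assert np.all(model.variances_ > 0)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            gnb_fit(np.array([[1.0], [2.0]]), np.array(["a", "a"]))


class TestPredict:
    def test_query_at_class_mean_wins(self):
        model = gnb_fit(TOY_X, TOY_Y)
        label, post = gnb_predict(model, [2.0, 2.0])
        assert label == "a"
        assert post[0] > 0.99
        assert abs(post.sum() - 1.0) < 1e-9

    def test_posterior_matches_direct_density_evaluation(self):
        # brute-force: prior * product of Gaussian densities, normalized
        X = np.array([[0.0], [0.4], [1.1], [0.9], [1.6]])
        y = np.array(["a", "a", "b", "b", "b"])
        model = gnb_fit(X, y)
        for q in (-0.5, 0.2, 0.7, 1.3, 2.5):
            _, post = gnb_predict(model, [q])
            raw = np.array(
                [
                    model.priors_[i]
                    * norm.pdf(q, model.means_[i, 0], np.sqrt(model.variances_[i, 0]))
                    for i in range(2)
                ]
            )
            np.testing.assert_allclose(post, raw / raw.sum(), atol=1e-9)

    def test_translation_invariance(self):
        model = gnb_fit(TOY_X, TOY_Y)
        shifted = gnb_fit(TOY_X + [100.0, 0.0], TOY_Y)
        for q in TOY_X:
            assert model.predict([q])[0] == shifted.predict([q + [100.0, 0.0]])[0]

    def test_log_space_matches_direct_product(self):
        # on data where the direct product cannot underflow
        model = gnb_fit(TOY_X, TOY_Y)
        q = np.array([[4.0, 5.0]])
        direct = np.array(
            [
                model.priors_[i]
                * np.prod(
                    norm.pdf(q[0], model.means_[i], np.sqrt(model.variances_[i]))
                )
                for i in range(2)
            ]
        )
        np.testing.assert_allclose(
            model.predict_proba(q)[0], direct / direct.sum(), atol=1e-9
        )

    def test_agrees_with_reference_implementation(self, rng):
        X = rng.normal(size=(300, 4)) + np.repeat(np.eye(4)[:3] * 2, 100, axis=0)
        y = np.repeat(["a", "b", "c"], 100)
        ours = gnb_fit(X, y)
        ref = SkGaussianNB().fit(X, y)
        assert (ours.predict(X) == ref.predict(X)).all()
        np.testing.assert_allclose(ours.predict_proba(X), ref.predict_proba(X), atol=1e-6)

    def test_tie_broken_by_class_order(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        y = np.array(["b", "b", "a", "a"])  # identical class-conditionals
        model = gnb_fit(X, y)
        assert model.predict([[1.0]])[0] == "a"  # sorted order wins

    def test_dimension_mismatch_rejected(self):
        model = gnb_fit(TOY_X, TOY_Y)
        with pytest.raises(InvalidInputError):
            model.predict([[1.0, 2.0, 3.0]])

    def test_unfitted_model_rejected(self):
        with pytest.raises(InvalidInputError):
            GaussianNaiveBayes().predict([[0.0]])


class TestBayesRateConvergence:
    def test_accuracy_approaches_analytic_bayes_rate(self, rng):
        # two 1-D Gaussians, means +-1, unit variance, equal priors:
        # Bayes accuracy = Phi(1)
        n = 5000
        X = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])[:, None]
        y = np.repeat(["neg", "pos"], n)
        model = gnb_fit(X, y)
        Xt = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])[:, None]
        acc = (model.predict(Xt) == y).mean()
        assert abs(acc - norm.cdf(1.0)) < 0.02


class TestPersistence:
    def test_json_round_trip(self, tmp_path):
        model = gnb_fit(TOY_X, TOY_Y)
        path = tmp_path / "gnb.json"
        model.save(path)
        loaded = GaussianNaiveBayes.load(path)
        np.testing.assert_allclose(loaded.means_, model.means_)
        np.testing.assert_allclose(loaded.variances_, model.variances_)
        assert (loaded.predict(TOY_X) == model.predict(TOY_X)).all()

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ConfigurationError):
            GaussianNaiveBayes.load(path)


class TestHarness:
    def test_default_specs_cover_four_kinds(self):
        assert [s.kind for s in default_specs()] == ["gnb", "svm_rbf", "knn", "dtree"]
        svm = default_specs()[1]
        assert svm.params == {"C": 10.0, "gamma": 1.0}
        assert default_specs()[3].params == {"max_depth": 5}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierSpec("forest")

    def test_knn_neighbor_rule(self):
        # round(sqrt(48600)) = 220 for the benchmark's training folds
        assert knn_k(48600) == 220
        assert knn_k(100) == 10
        assert knn_k(1) == 1

    def test_gnb_spec_delegates_to_in_house_model(self):
        model = train_classifier(ClassifierSpec("gnb"), TOY_X, TOY_Y)
        assert isinstance(model, GaussianNaiveBayes)
        reference = gnb_fit(TOY_X, TOY_Y)
        assert (model.predict(TOY_X) == reference.predict(TOY_X)).all()

    def test_dtree_separates_linearly_separable_toy_data(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(3, 0.1, (50, 2))])
        y = np.repeat(["lo", "hi"], 50)
        model = train_classifier(ClassifierSpec("dtree", {"max_depth": 5}), X, y)
        assert (model.predict(X) == y).all()

    def test_knn_with_explicit_k(self):
        model = train_classifier(ClassifierSpec("knn", {"k": 3}), TOY_X, TOY_Y)
        assert model.n_neighbors_ == 3
        assert (model.predict(TOY_X) == TOY_Y).all()

    def test_unknown_params_rejected(self):
        with pytest.raises(ConfigurationError):
            train_classifier(ClassifierSpec("dtree", {"depth": 3}), TOY_X, TOY_Y)
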