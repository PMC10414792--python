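import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB

import neurostack.stacking as stacking
from neurostack.cnn_base import default_base_configs
from neurostack.evaluation import auc
from neurostack.stacking import (
    GNBModel,
    GNBParams,
    META_FEATURE_ORDER,
    StackedModel,
    fit_meta,
    gnb_fit,
    gnb_predict_proba,
    make_meta_features,
    stacked_predict,
)
from neurostack.synthetic_data import generate_meta_features


def gaussian_density(x, mu, var):
    return np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)


def brute_force_posterior(params, x):
    """Direct (non-log) evaluation of prior x product-of-Gaussians."""
    joint = []
    for c in (0, 1):
        dens = np.prod(
            [gaussian_density(x[j], params.means[c, j], params.variances[c, j])
             for j in range(len(x))]
        )
        joint.append(params.class_priors[c] * dens)
    return joint[1] / (joint[0] + joint[1])


class TestGNBFit:
    def test_first_moments_match_direct_formulas(self):
        X = np.array([[0.1, 0.3, 0.5, 0.7],
                      [0.2, 0.4, 0.6, 0.8],
                      [0.8, 0.8, 0.8, 0.8],
                      [0.9, 0.9, 0.9, 0.9]])
        y = [0, 0, 1, 1]
        params = gnb_fit(X, y, var_smoothing=1e-10)
        assert params.means[0, 0] == pytest.approx(0.15)
        # population variance of {0.1, 0.2} = 0.0025, plus smoothing
        assert params.variances[0, 0] == pytest.approx(0.0025 + 1e-10)

    def test_priors_are_class_frequencies(self):
        X = np.tile(np.arange(10)[:, None] / 10, (1, 4))
        y = [1] * 6 + [0] * 4
        params = gnb_fit(X, y)
        np.testing.assert_allclose(params.class_priors, [0.4, 0.6])

    def test_identical_class_distributions_give_equal_means(self):
        rows = np.random.default_rng(0).random((5, 4))
        X = np.vstack([rows, rows])
        y = [0] * 5 + [1] * 5
        params = gnb_fit(X, y)
        np.testing.assert_allclose(params.means[0], params.means[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gnb_fit(np.random.default_rng(0).random((4, 4)), [1, 1, 1, 1])

    def test_params_invariants_enforced(self):
        with pytest.raises(ValueError):
            GNBParams(class_priors=np.array([0.7, 0.7]),
                      means=np.zeros((2, 4)), variances=np.ones((2, 4)),
                      var_smoothing=1e-9)


class TestGNBPredict:
    def test_mirror_symmetric_classes_posterior_half_at_midpoint(self):
        params = GNBParams(
            class_priors=np.array([0.5, 0.5]),
            means=np.array([[0.2], [0.8]]),
            variances=np.array([[0.01], [0.01]]),
            var_smoothing=1e-12,
        )
        assert gnb_predict_proba(params, np.array([0.5])) == pytest.approx(0.5)

    def test_identical_class_conditionals_return_prior(self):
        params = GNBParams(
            class_priors=np.array([0.7, 0.3]),
            means=np.array([[0.5], [0.5]]),
            variances=np.array([[0.02], [0.02]]),
            var_smoothing=1e-12,
        )
        assert gnb_predict_proba(params, np.array([0.1])) == pytest.approx(0.3)

    def test_one_feature_toy_matches_density_oracle(self):
        var = 0.04
        params = GNBParams(
            class_priors=np.array([0.5, 0.5]),
            means=np.array([[0.15], [0.85]]),
            variances=np.array([[var], [var]]),
            var_smoothing=1e-12,
        )
        x = np.array([0.85])
        expected = brute_force_posterior(params, x)
        assert gnb_predict_proba(params, x) == pytest.approx(expected, rel=1e-12)

    def test_log_space_matches_brute_force_on_random_params(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pr = rng.random()
            params = GNBParams(
                class_priors=np.array([pr, 1 - pr]),
                means=rng.random((2, 4)),
                variances=0.01 + rng.random((2, 4)) * 0.1,
                var_smoothing=1e-12,
            )
            x = rng.random(4)
            expected = brute_force_posterior(params, x)
            assert gnb_predict_proba(params, x) == pytest.approx(expected, rel=1e-9)

    def test_posteriors_over_classes_sum_to_one(self):
        rng = np.random.default_rng(5)
        X, y = generate_meta_features(60, separation=0.4, seed=5)
        params = gnb_fit(X, y)
        p1 = gnb_predict_proba(params, X)
        # P(class 0) computed by label swap must complement P(class 1)
        swapped = gnb_fit(X, 1 - y)
        p0 = gnb_predict_proba(swapped, X)
        np.testing.assert_allclose(p1 + p0, 1.0, atol=1e-12)

    def test_monotone_in_feature_with_shared_variances(self):
        params = GNBParams(
            class_priors=np.array([0.5, 0.5]),
            means=np.array([[0.3, 0.5, 0.5, 0.5], [0.7, 0.5, 0.5, 0.5]]),
            variances=np.full((2, 4), 0.02),
            var_smoothing=1e-12,
        )
        grid = np.linspace(0, 1, 21)
        X = np.column_stack([grid, *[np.full(21, 0.5)] * 3])
        p = gnb_predict_proba(params, X)
        assert np.all(np.diff(p) > 0)

    def test_agrees_with_sklearn_gaussian_nb(self):
        X, y = generate_meta_features(120, separation=0.5, seed=2)
        params = gnb_fit(X, y)  # default smoothing mirrors sklearn's convention
        ours = gnb_predict_proba(params, X)
        ref = GaussianNB().fit(X, y).predict_proba(X)[:, 1]
        np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestFitMeta:
    def test_all_five_algorithms_return_probabilities(self):
        X, y = generate_meta_features(80, separation=0.5, seed=1)
        for algorithm in stacking.META_ALGORITHMS:
            model = fit_meta(algorithm, X, y, seed=0)
            p = np.asarray(model.predict_proba(X))
            assert p.shape == (80,)
            assert np.all((p >= 0) & (p <= 1))

    def test_unknown_algorithm_rejected(self):
        X, y = generate_meta_features(20, separation=0.5, seed=1)
        with pytest.raises(ValueError, match="unknown"):
            fit_meta("svm", X, y)

    def test_gnb_on_separated_meta_features_cv_auc(self):
        from sklearn.model_selection import StratifiedKFold

        X, y = generate_meta_features(200, separation=0.6, seed=4)
        scores = np.zeros(len(y))
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            scores[te] = fit_meta("gnb", X[tr], y[tr]).predict_proba(X[te])
        assert auc(y, scores) >= 0.95


class TestMetaFeatures:
    def test_shape_bounds_and_determinism(self, motif_records):
        records = motif_records[:40] + motif_records[100:140]
        configs = default_base_configs(seed=0, epochs=2)
        X1, y1 = make_meta_features(records, configs, k=2, seed=0)
        X2, y2 = make_meta_features(records, configs, k=2, seed=0)
        assert X1.shape == (80, 4)
        assert np.all((X1 >= 0) & (X1 <= 1))
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_every_prediction_is_out_of_fold(self, motif_records, monkeypatch):
        """Leakage guard: no sample may be scored by a model that saw it."""

        class FakeModel:
            def __init__(self, train_rows):
                self.train_rows = {row.tobytes() for row in train_rows}

        def fake_train(X, y, config):
            return FakeModel(np.asarray(X))

        def fake_predict(model, X):
            return np.array(
                [1.0 if row.tobytes() in model.train_rows else 0.0 for row in np.asarray(X)]
            )

        monkeypatch.setattr(stacking, "train_cnn", fake_train)
        monkeypatch.setattr(stacking, "predict_proba", fake_predict)
        records = motif_records[:20] + motif_records[100:120]
        meta_X, _ = make_meta_features(records, default_base_configs(epochs=1), k=4, seed=0)
        assert np.all(meta_X == 0.0)  # 1.0 would mean a leaked training sample


class TestStackedModel:
    def test_posterior_tie_classifies_positive(self, motif_records):
        records = motif_records[:10] + motif_records[100:110]
        configs = default_base_configs(seed=0, epochs=1)
        model = stacking.fit_stacked(records, configs, k=2, seed=0)

        class HalfMeta:
            def predict_proba(self, X):
                return np.full(len(np.atleast_2d(X)), 0.5)

        tied = StackedModel(
            base_models=model.base_models,
            embedding_table=model.embedding_table,
            meta=HalfMeta(),
        )
        probs, labels = stacked_predict(tied, records[:4])
        assert np.all(probs == 0.5)
        assert np.all(labels == 1)

    def test_base_models_must_cover_all_encoders(self, motif_records):
        records = motif_records[:6] + motif_records[100:106]
        model = stacking.fit_stacked(
            records, default_base_configs(epochs=1), k=2, seed=0
        )
        incomplete = dict(model.base_models)
        incomplete.pop("ggap")
        with pytest.raises(ValueError, match="encoders"):
            StackedModel(
                base_models=incomplete,
                embedding_table=model.embedding_table,
                meta=model.meta,
            )

    def test_predictions_align_with_record_count(self, motif_records):
        records = motif_records[:8] + motif_records[100:108]
        model = stacking.fit_stacked(records, default_base_configs(epochs=1), k=2, seed=0)
        probs, labels = stacked_predict(model, records)
        assert probs.shape == labels.shape == (16,)
        assert np.all((probs >= 0) & (probs <= 1))
        assert set(np.unique(labels)) <= {0, 1}
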