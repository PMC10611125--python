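"""CNN classifier contracts: shapes, training sanity, folds, metrics."""

import numpy as np
import pytest

from szuq.classifier import (CNNSegmentClassifier, classification_metrics,
                             lopo_folds, predict_segments)


class TestArchitecture:
    def test_two_logits_and_feature_dim(self):
        clf = CNNSegmentClassifier()
        rng = np.random.default_rng(0)
        model, tap, fdim = clf._build(22, 256, rng)
        out = model.forward(np.zeros((3, 1, 22, 256), dtype=np.float32))
        assert out.shape == (3, 2)
        # feature_dim equals the flattened final conv output:
        # channel extent 22-2+1=21; time 256->126->62->26->3; 64 filters
        assert fdim == 64 * 21 * 3

    def test_same_seed_identical_initial_parameters(self):
        clf = CNNSegmentClassifier(
            filters=(4, 4, 4, 4), kernels=((3, 2), (3, 1), (3, 1), (3, 1)),
            fc_width=8, seed=5)
        m1, _, _ = clf._build(8, 64, np.random.default_rng(5))
        m2, _, _ = clf._build(8, 64, np.random.default_rng(5))
        for (p1, _), (p2, _) in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1, p2)

    def test_oversized_kernel_rejected(self):
        clf = CNNSegmentClassifier(kernels=((5, 2), (3, 1), (10, 1), (300, 1)))
        with pytest.raises(ValueError, match="exceeds"):
            clf._build(22, 256, np.random.default_rng(0))


class TestTraining:
    def test_overfits_separable_toy_set(self, tiny_classifier):
        clf, X, y = tiny_classifier
        assert (clf.predict(X) == y).mean() == 1.0
        assert clf.loss_history_[-1] < clf.loss_history_[0]

    def test_same_seed_same_final_loss(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((32, 3, 64)).astype(np.float32)
        y = np.array([0, 1] * 16)
        kw = dict(filters=(2, 2, 2, 2), kernels=((3, 2), (3, 1), (3, 1), (3, 1)),
                  fc_width=8, epochs=3, seed=11)
        a = CNNSegmentClassifier(**kw).fit(X, y)
        b = CNNSegmentClassifier(**kw).fit(X, y)
        assert a.loss_history_ == b.loss_history_

    def test_single_class_training_rejected(self):
        X = np.zeros((8, 3, 32), dtype=np.float32)
        with pytest.raises(ValueError, match="both classes"):
            CNNSegmentClassifier().fit(X, np.zeros(8, dtype=int))


class TestPrediction:
    def test_threshold_and_tie_rule(self, tiny_classifier):
        clf, X, _ = tiny_classifier
        probs = clf.predict_proba(X)
        np.testing.assert_array_equal(clf.predict(X),
                                      (probs[:, 1] >= 0.5).astype(int))

    def test_features_attached_per_segment(self, tiny_classifier):
        clf, X, _ = tiny_classifier
        preds = predict_segments(clf, X[:5])
        assert len(preds) == 5
        for p in preds:
            assert p.features.shape == (clf.feature_dim_,)
            assert p.label_hat == int(p.prob >= 0.5)

    def test_feature_extraction_is_pure(self, tiny_classifier):
        clf, X, _ = tiny_classifier
        np.testing.assert_array_equal(clf.transform(X[:8]),
                                      clf.transform(X[:8]))

    def test_shape_mismatch_rejected(self, tiny_classifier):
        clf, X, _ = tiny_classifier
        with pytest.raises(ValueError, match="match"):
            clf.predict(np.zeros((2, 5, 64), dtype=np.float32))

    def test_mc_dropout_seeded_and_dispersed(self, tiny_classifier):
        clf, X, _ = tiny_classifier
        a = clf.mc_dropout_proba(X[:6], passes=5, seed=9)
        b = clf.mc_dropout_proba(X[:6], passes=5, seed=9)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (5, 6, 2)
        with pytest.raises(ValueError, match="passes"):
            clf.mc_dropout_proba(X[:2], passes=1)


class TestSerialization:
    def test_checkpoint_round_trip(self, tiny_classifier, tmp_path):
        clf, X, _ = tiny_classifier
        path = tmp_path / "model.joblib"
        clf.save(path)
        back = type(clf).load(path)
        np.testing.assert_array_equal(back.predict_proba(X[:8]),
                                      clf.predict_proba(X[:8]))
        assert back.feature_dim_ == clf.feature_dim_

    def test_unfitted_save_rejected(self, tmp_path):
        with pytest.raises(Exception):
            CNNSegmentClassifier().save(tmp_path / "x.joblib")


class TestLopoFolds:
    def test_one_fold_per_patient(self):
        folds = lopo_folds([f"p{i}" for i in range(23)])
        assert len(folds) == 23
        assert {t for _, t in folds} == {f"p{i}" for i in range(23)}

    def test_three_patient_enumeration(self):
        folds = lopo_folds(["a", "b", "c"])
        assert folds == [(["b", "c"], "a"), (["a", "c"], "b"),
                         (["a", "b"], "c")]

    def test_no_leakage(self):
        for train, test in lopo_folds(list("abcdef")):
            assert test not in train

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            lopo_folds(["only"])


class TestClassificationMetrics:
    def test_formula_evaluation(self):
        # TP=2, FP=1, FN=1, TN=6
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        yhat = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        m = classification_metrics(y, yhat)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(6 / 7)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        y = [0, 1, 0, 1]
        m = classification_metrics(y, y, [0.1, 0.9, 0.2, 0.8])
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "f1", "auc"))

    def test_constant_probs_give_chance_auc(self):
        m = classification_metrics([0, 1, 0, 1], [0, 1, 0, 1],
                                   [0.5, 0.5, 0.5, 0.5])
        assert m["auc"] == 0.5

    def test_degenerate_labels_marked_undefined(self):
        m = classification_metrics([0, 0], [0, 0], [0.1, 0.2])
        assert np.isnan(m["sensitivity"]) and np.isnan(m["auc"])
        assert m["specificity"] == 1.0
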