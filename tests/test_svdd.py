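"""Deep SVDD detectors and confusion-group partitioning."""

import numpy as np
import pytest

from szuq.svdd import (DeepSVDD, GroupedUncertaintyModel, fit_deep_svdd,
                       partition_by_outcome, svdd_flag)


@pytest.fixture(scope="module")
def cluster_svdd():
    """Detector fitted on one tight Gaussian cluster (module-scoped)."""
    rng = np.random.default_rng(0)
    A = (rng.standard_normal((400, 16)) + 4.0).astype(np.float32)
    model = DeepSVDD(latent_dim=8, hidden=(32, 16), seed=1).fit(A)
    return model, A


class TestPartition:
    def test_confusion_outcome_definitions(self):
        feats = np.arange(8, dtype=float).reshape(4, 2)
        part = partition_by_outcome([1, 0, 0, 1], [1, 1, 0, 0], feats)
        assert part.sizes() == {"tp": 1, "fp": 1, "tn": 1, "fn": 1}
        np.testing.assert_array_equal(part.tp, [[0, 1]])
        np.testing.assert_array_equal(part.fn, [[6, 7]])

    def test_all_correct_leaves_error_groups_empty(self):
        feats = np.zeros((4, 2))
        part = partition_by_outcome([1, 0, 1, 0], [1, 0, 1, 0], feats)
        assert part.sizes()["fp"] == 0 and part.sizes()["fn"] == 0

    def test_partition_covers_input(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        yhat = rng.integers(0, 2, 50)
        part = partition_by_outcome(y, yhat, rng.random((50, 3)))
        assert sum(part.sizes().values()) == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            partition_by_outcome([0, 1], [0], np.zeros((2, 2)))


class TestDeepSVDD:
    def test_quantile_calibration(self, cluster_svdd):
        model, A = cluster_svdd
        frac_in = (model.train_distances_ <= model.rho_).mean()
        assert abs(frac_in - model.q) <= 0.02

    def test_seeded_determinism(self, cluster_svdd):
        model, A = cluster_svdd
        again = DeepSVDD(latent_dim=8, hidden=(32, 16), seed=1).fit(A)
        np.testing.assert_array_equal(model.center_, again.center_)
        assert model.rho_ == again.rho_

    def test_far_outlier_flagged(self, cluster_svdd):
        model, A = cluster_svdd
        outlier = A.max() * 10 * np.ones((1, 16), dtype=np.float32)
        assert model.predict(outlier)[0] == 1
        assert model.distances(outlier)[0] > model.rho_

    def test_closest_training_point_accepted(self, cluster_svdd):
        model, A = cluster_svdd
        d = model.distances(A)
        assert svdd_flag(model, A[np.argmin(d)]) == 0

    def test_boundary_counts_as_in_distribution(self, cluster_svdd):
        model, A = cluster_svdd
        d = model.distances(A)
        probe = A[np.argsort(d)[len(d) // 2]]
        original = model.rho_
        try:
            model.rho_ = float(model.distances(probe[None])[0])
            assert model.predict(probe[None])[0] == 0
        finally:
            model.rho_ = original

    def test_flag_monotone_in_distance(self, cluster_svdd):
        model, A = cluster_svdd
        rng = np.random.default_rng(2)
        probes = (rng.standard_normal((100, 16)) * 3 + 4).astype(np.float32)
        d = model.distances(probes)
        flags = model.predict(probes)
        order = np.argsort(d)
        assert np.all(np.diff(flags[order]) >= 0)

    def test_latent_dim_must_be_below_feature_dim(self):
        with pytest.raises(ValueError, match="latent_dim"):
            DeepSVDD(latent_dim=16).fit(np.zeros((30, 16), dtype=np.float32))

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError, match="quantile"):
            DeepSVDD(q=1.5, latent_dim=2).fit(np.zeros((30, 8),
                                                       dtype=np.float32))

    def test_shape_mismatch_rejected(self, cluster_svdd):
        model, _ = cluster_svdd
        with pytest.raises(ValueError, match="feature length"):
            model.distances(np.zeros((2, 5), dtype=np.float32))

    def test_separated_cluster_mostly_flagged(self):
        """Two isotropic clusters whose centers are 5 within-cluster SDs
        apart: at least 90% of the second cluster is out-of-distribution."""
        rng = np.random.default_rng(2)
        A = (rng.standard_normal((500, 8)) + 3.0).astype(np.float32)
        shift = np.zeros(8, dtype=np.float32)
        shift[0] = 5.0
        B = (rng.standard_normal((300, 8)) + 3.0 + shift).astype(np.float32)
        model = fit_deep_svdd(A, latent_dim=6, hidden=(64, 32), seed=1)
        assert model.predict(B).mean() >= 0.90

    def test_functional_wrapper_returns_fitted_model(self):
        rng = np.random.default_rng(3)
        model = fit_deep_svdd(rng.random((60, 10)).astype(np.float32),
                              latent_dim=4, q=0.9, epochs=5, seed=2)
        assert model.rho_ > 0 and model.q == 0.9


class TestGroupedModel:
    def test_degenerate_group_always_flagged(self):
        rng = np.random.default_rng(0)
        feats = (rng.standard_normal((60, 12)) + 2).astype(np.float32)
        y = np.array([0] * 55 + [1] * 5)      # tiny seizure group
        yhat = y.copy()                        # perfect predictions
        model = GroupedUncertaintyModel(latent_dim=6, hidden=(16, 8),
                                        min_group_size=20, epochs=5,
                                        pretrain_epochs=5, seed=1)
        model.fit(feats, y, yhat)
        assert set(model.degenerate_groups_) == {"tp", "fp", "fn"}
        assert model.svdds_["tn"] is not None
        flags = model.flags(feats[:3])
        assert flags.shape == (3, 4)
        np.testing.assert_array_equal(flags[:, 0], 1)  # tp degenerate
        np.testing.assert_array_equal(flags[:, 1], 1)  # fp degenerate
        np.testing.assert_array_equal(flags[:, 3], 1)  # fn degenerate

    def test_bundle_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        feats = (rng.standard_normal((80, 12)) + 2).astype(np.float32)
        y = np.array([0] * 60 + [1] * 20)
        model = GroupedUncertaintyModel(latent_dim=4, hidden=(16, 8),
                                        min_group_size=20, epochs=3,
                                        pretrain_epochs=3, seed=4)
        model.fit(feats, y, y)
        path = tmp_path / "bundle.joblib"
        model.save(path)
        back = GroupedUncertaintyModel.load(path)
        np.testing.assert_array_equal(back.flags(feats[:7]),
                                      model.flags(feats[:7]))
        assert back.group_sizes_ == model.group_sizes_

    def test_group_sizes_recorded(self):
        rng = np.random.default_rng(1)
        feats = rng.random((40, 6)).astype(np.float32)
        y = np.array([0, 1] * 20)
        yhat = np.array([0] * 40)
        model = GroupedUncertaintyModel(latent_dim=3, hidden=(8, 4),
                                        min_group_size=100, seed=0)
        model.fit(feats, y, yhat)
        assert model.group_sizes_ == {"tp": 0, "fp": 0, "tn": 20, "fn": 20}
        assert set(model.degenerate_groups_) == {"tp", "fp", "tn", "fn"}
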