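"""Deep SVDD out-of-distribution detectors over classifier features.

Deep support vector data description (one-class variant): a small bias-free
encoder is trained to map in-distribution feature vectors close to a fixed
center ``c`` in latent space, minimizing the mean squared distance plus
weight decay.  ``c`` is frozen at the mean latent output of the untrained
encoder's first pass — re-centering during training is forbidden, and the
encoder carries no additive bias terms, both standard guards against the
trivial "hypersphere collapse" solution where the encoder maps everything
onto the center.  A query is flagged out-of-distribution when its squared
latent distance exceeds ``rho``, the ``q``-quantile (default 0.95) of the
training distances.

The grouped model fits one detector per confusion group of the trained
classifier's *training-set* predictions — true/false positives/negatives —
so each detector learns the feature distribution of patterns the classifier
got right or wrong in a specific way.  Groups too small to characterize
(for example the handful of false positives of a near-perfect classifier)
are degenerate: their flag is fixed at 1 (out-of-distribution) and the
condition is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "DeepSVDD",
    "SVDDEnsemble",
    "GroupPartition",
    "partition_by_outcome",
    "fit_deep_svdd",
    "svdd_flag",
    "GroupedUncertaintyModel",
    "GROUPS",
]

GROUPS = ("tp", "fp", "tn", "fn")


class HypersphereCollapseError(RuntimeError):
    """Encoder output variance fell below the collapse floor during fit."""


class DeepSVDD(BaseEstimator, OutlierMixin):
    """One-class Deep SVDD anomaly detector on feature vectors.

    Parameters
    ----------
    hidden : tuple of int
        Widths of the two hidden encoder layers.
    latent_dim : int
        Latent space dimension; must be below the input feature dimension.
    q : float
        Training-distance quantile that sets the threshold ``rho``.
    rho_margin : float
        Decision threshold as a multiple of ``rho`` (1.0 = the plain
        in-sample quantile; above 1 leaves room for the distance inflation
        of data from unseen sources such as new patients).
    lr, epochs, batch_size : optimizer settings (Adam).
    pretrain_epochs : int
        Autoencoder reconstruction epochs before the one-class phase.
    weight_decay : float
        L2 penalty on encoder weights (part of the one-class objective).
    collapse_floor : float
        Minimum allowed ratio of final to initial latent standard deviation;
        below it the fit fails with :class:`HypersphereCollapseError`.
    seed : int

    Attributes
    ----------
    center_ : ndarray, shape (latent_dim,)
        Fixed hypersphere center.
    rho_ : float
        Squared-distance threshold (q-quantile of training distances).
    train_distances_ : ndarray
        Final squared distances of the training set.
    """

    def __init__(self, hidden=(128, 64), latent_dim=32, q=0.95,
                 rho_margin=1.0, lr=1e-3, epochs=30, pretrain_epochs=30,
                 batch_size=64, weight_decay=1e-5, collapse_floor=1e-3,
                 standardize=True, seed=0):
        self.hidden = hidden
        self.latent_dim = latent_dim
        self.q = q
        self.rho_margin = rho_margin
        self.lr = lr
        self.epochs = epochs
        self.pretrain_epochs = pretrain_epochs
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.collapse_floor = collapse_floor
        self.standardize = standardize
        self.seed = seed

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def _pretrain(self, X: np.ndarray, rng: np.random.Generator) -> None:
        """Autoencoder pretraining: anchors the latent map to input structure
        so distance-to-center remains meaningful off the training manifold."""
        d = X.shape[1]
        h1, h2 = self.hidden
        decoder = nn.Sequential([
            nn.Dense(self.latent_dim, h2, rng, bias=False), nn.LeakyReLU(),
            nn.Dense(h2, h1, rng, bias=False), nn.LeakyReLU(),
            nn.Dense(h1, d, rng, bias=False),
        ])
        opt = nn.Adam(self.encoder_.params() + decoder.params(), lr=self.lr,
                      weight_decay=self.weight_decay)
        n = X.shape[0]
        for _ in range(self.pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                z = self.encoder_.forward(X[idx], train=True, rng=rng)
                xhat = decoder.forward(z, train=True, rng=rng)
                diff = (xhat - X[idx]) / (idx.size * d)
                grad_z = decoder.backward(2.0 * diff)
                self.encoder_.backward(grad_z)
                opt.step()

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError("expected (n, feature_dim) input")
        n, d = X.shape
        if self.latent_dim >= d:
            raise ValueError(
                f"latent_dim {self.latent_dim} must be below feature "
                f"dimension {d}"
            )
        if not 0 < self.q < 1:
            raise ValueError("quantile q must lie in (0, 1)")
        # per-dimension standardization (floored so near-constant feature
        # dimensions cannot blow up); conditions the encoder and makes
        # latent distances comparable across feature dimensions
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.maximum(sd, 0.05 * sd.mean() + 1e-12)
        else:
            self.mean_ = np.zeros(X.shape[1], dtype=np.float32)
            self.scale_ = np.ones(X.shape[1], dtype=np.float32)
        X = self._scale(X).astype(np.float32)
        rng = np.random.default_rng(self.seed)
        h1, h2 = self.hidden
        self.encoder_ = nn.Sequential([
            nn.Dense(d, h1, rng, bias=False), nn.LeakyReLU(),
            nn.Dense(h1, h2, rng, bias=False), nn.LeakyReLU(),
            nn.Dense(h2, self.latent_dim, rng, bias=False),
        ])
        if self.pretrain_epochs:
            self._pretrain(X, rng)
        self.n_features_in_ = d
        self._one_class_phase(X, rng)
        return self

    def _one_class_phase(self, X: np.ndarray, rng: np.random.Generator
                         ) -> None:
        """Fix the center, contract toward it, set rho (X pre-standardized)."""
        n = X.shape[0]
        z0 = self.encoder_.forward(X)
        self.center_ = z0.mean(axis=0).astype(np.float32)  # frozen hereafter
        init_std = float(z0.std())
        opt = nn.Adam(self.encoder_.params(), lr=self.lr,
                      weight_decay=self.weight_decay)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                z = self.encoder_.forward(X[idx], train=True, rng=rng)
                diff = z - self.center_
                # objective: mean ||z - c||^2 (weight decay via optimizer)
                self.encoder_.backward(2.0 * diff / idx.size)
                opt.step()
        z = self.encoder_.forward(X)
        if init_std > 0 and float(z.std()) < self.collapse_floor * init_std:
            raise HypersphereCollapseError(
                "encoder output collapsed toward the center; refit with "
                "lower lr/weight_decay or more data"
            )
        self.train_distances_ = np.sum((z - self.center_) ** 2, axis=1)
        self.rho_ = float(np.quantile(self.train_distances_, self.q))

    def refit_one_class(self, X, seed: int | None = None) -> "DeepSVDD":
        """Re-run the one-class phase on a subset, keeping the pretrained
        encoder and standardization.

        This is how a *group*-specific detector is derived from a base
        detector pretrained on the full training feature set: the shared
        autoencoder anchors the latent map for all training data (so data
        the group never contained cannot land arbitrarily close to the
        group's center), then the contraction and threshold are the
        group's own.
        """
        check_is_fitted(self, "encoder_")
        X = np.asarray(X, dtype=np.float32)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        self._one_class_phase(self._scale(X).astype(np.float32), rng)
        return self

    def distances(self, X) -> np.ndarray:
        """Squared latent distance to the center for each row."""
        check_is_fitted(self, "center_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match fitted "
                f"dimension {self.n_features_in_}"
            )
        z = self.encoder_.forward(self._scale(X).astype(np.float32))
        return np.sum((z - self.center_) ** 2, axis=1)

    @property
    def threshold_(self) -> float:
        """Decision threshold: ``rho_margin`` times the rho quantile.

        A margin above 1 leaves head-room for the distance inflation that
        legitimate *unseen-source* data (a new patient) shows relative to
        the in-sample quantile; genuinely out-of-distribution data sits
        several multiples of rho away.
        """
        return self.rho_margin * self.rho_

    def predict(self, X) -> np.ndarray:
        """Binary flags: 1 out-of-distribution (d > threshold), 0 in.

        The boundary ``d == threshold`` counts as in-distribution.
        """
        return (self.distances(X) > self.threshold_).astype(int)

    def decision_function(self, X) -> np.ndarray:
        """Signed margin ``threshold - d``; negative means OOD."""
        return self.threshold_ - self.distances(X)


class SVDDEnsemble(BaseEstimator, OutlierMixin):
    """Majority vote over independently seeded :class:`DeepSVDD` members.

    Small Deep SVDD encoders fitted on a few hundred high-dimensional
    feature vectors are volatile: the acceptance rate on slightly shifted
    data (an unseen patient) can swing widely with the initialization seed.
    A vote of ``n_votes`` members (flag 1 when the majority says
    out-of-distribution) keeps each member's one-class geometry intact while
    shrinking the seed-to-seed variance of the flag rates.  ``n_votes=1``
    degenerates to a single detector.
    """

    def __init__(self, n_votes: int = 3, seed: int = 0, **svdd_params):
        self.n_votes = n_votes
        self.seed = seed
        self.svdd_params = svdd_params

    def fit(self, X, y=None):
        if self.n_votes < 1 or self.n_votes % 2 == 0:
            raise ValueError("n_votes must be a positive odd number")
        seeds = np.random.SeedSequence(self.seed).spawn(self.n_votes)
        self.members_ = [
            DeepSVDD(seed=int(s.generate_state(1)[0] % (2 ** 31)),
                     **self.svdd_params).fit(X)
            for s in seeds
        ]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        votes = np.stack([m.predict(X) for m in self.members_])
        return (votes.sum(axis=0) * 2 > self.n_votes).astype(int)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.mean([m.decision_function(X) for m in self.members_],
                       axis=0)


@dataclass
class GroupPartition:
    """Training features split by the classifier's confusion outcome."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    indices: dict = field(default_factory=dict)

    def sizes(self) -> dict:
        return {g: getattr(self, g).shape[0] for g in GROUPS}


def partition_by_outcome(labels, predictions, features) -> GroupPartition:
    """Split training features into TP/FP/TN/FN by predicted vs true label."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    feats = np.asarray(features)
    if not (y.shape[0] == yhat.shape[0] == feats.shape[0]):
        raise ValueError("labels, predictions and features length mismatch")
    masks = {
        "tp": (y == 1) & (yhat == 1),
        "fp": (y == 0) & (yhat == 1),
        "tn": (y == 0) & (yhat == 0),
        "fn": (y == 1) & (yhat == 0),
    }
    return GroupPartition(
        **{g: feats[m] for g, m in masks.items()},
        indices={g: np.where(m)[0] for g, m in masks.items()},
    )


def fit_deep_svdd(features, latent_dim: int = 32, q: float = 0.95,
                  epochs: int = 60, seed: int = 0, **kwargs) -> DeepSVDD:
    """Functional wrapper around :class:`DeepSVDD`."""
    model = DeepSVDD(latent_dim=latent_dim, q=q, epochs=epochs, seed=seed,
                     **kwargs)
    return model.fit(np.asarray(features))


def svdd_flag(model: DeepSVDD, feature: np.ndarray) -> int:
    """Binary out-of-distribution flag for a single feature vector."""
    return int(model.predict(np.asarray(feature)[None] if
                             np.asarray(feature).ndim == 1 else feature)[0])


class GroupedUncertaintyModel(BaseEstimator):
    """Four per-confusion-group Deep SVDD detectors over classifier features.

    Fit on the trained classifier's *training-set* outcomes.  Groups with
    fewer than ``min_group_size`` members are degenerate: no detector is
    fitted and their flag is constantly 1 (out-of-distribution).

    Attributes
    ----------
    svdds_ : dict
        Group name -> fitted :class:`DeepSVDD` or ``None`` if degenerate.
    group_sizes_ : dict
        Group name -> member count.
    degenerate_groups_ : list of str
    """

    def __init__(self, latent_dim=32, q=0.95, rho_margin=1.0,
                 min_group_size=20, hidden=(128, 64), epochs=30,
                 pretrain_epochs=30, lr=1e-3, weight_decay=1e-5, n_votes=3,
                 seed=0):
        self.latent_dim = latent_dim
        self.q = q
        self.rho_margin = rho_margin
        self.min_group_size = min_group_size
        self.hidden = hidden
        self.epochs = epochs
        self.pretrain_epochs = pretrain_epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.n_votes = n_votes
        self.seed = seed

    def fit(self, features, labels, predictions, patient_ids=None):
        part = partition_by_outcome(labels, predictions, features)
        return self.fit_partition(part, patient_ids=patient_ids)

    def fit_partition(self, partition: GroupPartition, patient_ids=None):
        """Fit the four group detectors.

        ``patient_ids`` (aligned with the original training arrays) enables
        the leave-one-train-patient-out threshold calibration; without it
        the fixed ``rho_margin`` cap is used.
        """
        import copy

        self.svdds_ = {}
        self.group_sizes_ = partition.sizes()
        self.degenerate_groups_ = []
        self.margins_ = {}
        if patient_ids is not None:
            patient_ids = np.asarray(patient_ids)
        eligible = [g for g in GROUPS
                    if getattr(partition, g).shape[0] >= self.min_group_size]
        if not eligible:
            self.svdds_ = {g: None for g in GROUPS}
            self.degenerate_groups_ = list(GROUPS)
            return self
        all_feats = np.concatenate([getattr(partition, g) for g in GROUPS
                                    if getattr(partition, g).size])
        # shared autoencoder bases pretrained on the full training feature
        # set: the latent map is anchored for every training pattern, so a
        # group's detector cannot map data the group never contained
        # arbitrarily close to its center
        root = np.random.SeedSequence(self.seed)
        base_seeds = root.spawn(self.n_votes)
        bases = [
            DeepSVDD(hidden=self.hidden, latent_dim=self.latent_dim,
                     q=self.q, epochs=0,
                     pretrain_epochs=self.pretrain_epochs, lr=self.lr,
                     weight_decay=self.weight_decay,
                     seed=int(s.generate_state(1)[0] % (2 ** 31)),
                     ).fit(all_feats)
            for s in base_seeds
        ]
        group_seeds = root.spawn(len(GROUPS))
        for group, seq in zip(GROUPS, group_seeds):
            feats = getattr(partition, group)
            if feats.shape[0] < self.min_group_size:
                self.svdds_[group] = None
                self.degenerate_groups_.append(group)
                continue
            seqs = seq.spawn(self.n_votes + 1)
            members = []
            for base, s in zip(bases, seqs[:-1]):
                member = copy.deepcopy(base)
                member.epochs = self.epochs
                member.refit_one_class(
                    feats, seed=int(s.generate_state(1)[0] % (2 ** 31)))
                members.append(member)
            ensemble = SVDDEnsemble(n_votes=self.n_votes, seed=self.seed)
            ensemble.members_ = members
            self.svdds_[group] = ensemble
            self._calibrate_threshold(
                group, partition, bases[0], patient_ids,
                int(seqs[-1].generate_state(1)[0] % (2 ** 31)))
        return self

    def _new_patient_margin(self, feats, group_pids, base, seed: int
                            ) -> float | None:
        """Estimate the distance inflation a *new* patient's data shows.

        An in-sample quantile threshold is calibrated on patients that are
        in the training set; a held-out patient's data sits systematically
        farther out.  The inflation is estimated by leave-one-train-
        patient-out: contract a clone of the shared base on the group minus
        one patient, measure that patient's median distance relative to
        the clone's rho, and take the 75th percentile across patients — a
        threshold a typical new patient falls under, robust to one odd
        training patient.
        """
        import copy

        ratios = []
        for pid in np.unique(group_pids):
            held = group_pids == pid
            rest = feats[~held]
            if rest.shape[0] < self.min_group_size or held.sum() < 5:
                continue
            clone = copy.deepcopy(base)
            clone.epochs = self.epochs
            clone.refit_one_class(rest, seed=seed)
            d_held = clone.distances(feats[held])
            ratios.append(float(np.quantile(d_held, 0.5)) / clone.rho_)
        if not ratios:
            return None
        return float(np.quantile(ratios, 0.75))

    def _calibrate_threshold(self, group: str, partition: GroupPartition,
                             base, patient_ids, seed: int) -> None:
        """Set each member's decision threshold above its rho quantile.

        The margin comes from the leave-one-train-patient-out estimate when
        patient identities are available (falling back to the fixed
        ``rho_margin``), and is always capped so that at most ~5% of the
        *complementary class's* training features would pass as
        in-distribution — a seizure-group detector that accepts background
        makes every non-seizure prediction permanently unconfident, and
        vice versa.
        """
        feats = getattr(partition, group)
        margin = None
        if patient_ids is not None:
            group_pids = patient_ids[partition.indices[group]]
            margin = self._new_patient_margin(feats, group_pids, base, seed)
        if margin is None:
            margin = self.rho_margin
        margin = max(margin, 1.0)
        self.margins_[group] = margin
        if group in ("tp", "fn"):       # seizure groups: keep bg out
            opposite = np.concatenate([partition.tn, partition.fp])
        else:                            # non-seizure groups: keep ictal out
            opposite = np.concatenate([partition.tp, partition.fn])
        for member in self.svdds_[group].members_:
            thr = margin * member.rho_
            if opposite.shape[0] >= 10:
                d_out = member.distances(opposite)
                thr = min(thr, float(np.quantile(d_out, 0.05)))
            member.rho_margin = max(thr, member.rho_) / member.rho_

    def save(self, path) -> None:
        """Serialize the fitted per-group detector bundle to a file."""
        import joblib

        check_is_fitted(self, "svdds_")
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "GroupedUncertaintyModel":
        import joblib

        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a {cls.__name__}")
        return obj

    def flags(self, features) -> np.ndarray:
        """Per-group OOD flags, shape (n, 4), columns ordered TP, FP, TN, FN."""
        check_is_fitted(self, "svdds_")
        feats = np.asarray(features)
        if feats.ndim == 1:
            feats = feats[None]
        out = np.ones((feats.shape[0], len(GROUPS)), dtype=int)
        for j, group in enumerate(GROUPS):
            model = self.svdds_[group]
            if model is not None:
                out[:, j] = model.predict(feats)
        return out
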