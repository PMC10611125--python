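"""CNN seizure classifier, LOPO cross-validation folds, and per-fold metrics.

The classifier is a scikit-learn-style estimator over raw one-second
multichannel windows shaped ``(n, C, T)``.  Architecture: four convolutional
blocks — one spatial block whose kernel spans adjacent channel pairs, then
three purely temporal blocks with kernels of increasing time extent (short
kernels catch abrupt high-frequency discharges; long kernels catch rhythmic
spike-wave trains) — each followed by a rectifier and time-wise max pooling,
then dropout and a two-layer softmax head.  The flattened output of the final
convolutional block is the *internal feature representation* consumed by the
downstream out-of-distribution detectors.

Kernels are written ``(time_extent, channel_extent)`` throughout, matching
the convention used for EEG laid out as a channels x time image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "CNNSegmentClassifier",
    "SegmentPrediction",
    "predict_segments",
    "lopo_folds",
    "classification_metrics",
]


@dataclass
class SegmentPrediction:
    """Per-segment classifier output: label, class-1 probability, features."""

    label_hat: int
    prob: float
    features: np.ndarray


class CNNSegmentClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Convolutional seizure/non-seizure classifier for 1 s EEG windows.

    Parameters
    ----------
    filters : tuple of int
        Output channels of the four convolutional blocks.
    kernels : tuple of (time, channel) tuples
        Kernel extents per block; the first block spans channels, the rest
        are temporal.
    pool_t : int
        Time-wise max-pooling factor applied after every block.
    fc_width : int
        Width of the hidden fully connected layer.
    dropout : float
        Dropout rate before the fully connected head (also reused for
        Monte Carlo dropout at inference).
    lr, epochs, batch_size : float, int, int
        Adam learning rate, training epochs, and minibatch size.
    seed : int
        Seeds parameter initialization, shuffling, and dropout.

    Attributes
    ----------
    model_ : Sequential
        The fitted layer stack.
    feature_dim_ : int
        Length of the flattened final-conv-layer feature vector.
    loss_history_ : list of float
        Mean training cross-entropy per epoch.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(self, filters=(16, 32, 32, 64),
                 kernels=((5, 2), (3, 1), (10, 1), (20, 1)),
                 pool_t=2, fc_width=128, dropout=0.5,
                 lr=1e-4, epochs=100, batch_size=32, seed=0):
        self.filters = filters
        self.kernels = kernels
        self.pool_t = pool_t
        self.fc_width = fc_width
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # -- construction -----------------------------------------------------

    def _build(self, n_channels: int, n_times: int,
               rng: np.random.Generator) -> tuple[nn.Sequential, int, int]:
        """Build the layer stack; returns (model, tap_index, feature_dim)."""
        layers: list[nn.Layer] = []
        c_extent, t_extent, in_f = n_channels, n_times, 1
        for f, (kt, kc) in zip(self.filters, self.kernels):
            if kc > c_extent or kt > t_extent:
                raise ValueError(
                    f"kernel (t={kt}, c={kc}) exceeds block input extent "
                    f"(c={c_extent}, t={t_extent})"
                )
            layers += [nn.Conv2D(in_f, f, kc, kt, rng), nn.ReLU(),
                       nn.MaxPoolW(self.pool_t)]
            c_extent = c_extent - kc + 1
            t_extent = (t_extent - kt + 1) // self.pool_t
            in_f = f
        layers.append(nn.Flatten())
        tap = len(layers) - 1          # flattened final conv activations
        feature_dim = in_f * c_extent * t_extent
        if feature_dim <= 0:
            raise ValueError("architecture collapses the input to nothing")
        layers += [nn.Dropout(self.dropout),
                   nn.Dense(feature_dim, self.fc_width, rng), nn.ReLU(),
                   nn.Dense(self.fc_width, 2, rng)]
        return nn.Sequential(layers), tap, feature_dim

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = self._validate_input(np.asarray(X))
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training set must contain both classes (0 and 1)")
        rng = np.random.default_rng(self.seed)
        n, c, t = X.shape
        self.model_, self._tap, self.feature_dim_ = self._build(c, t, rng)
        self.input_shape_ = (c, t)
        self.classes_ = np.array([0, 1])
        opt = nn.Adam(self.model_.params(), lr=self.lr)
        Xb = X[:, None].astype(np.float32)  # (n, 1, C, T)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.model_.forward(Xb[idx], train=True, rng=rng)
                loss, grad = nn.softmax_xent(logits, y[idx])
                self.model_.backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        return self

    # -- inference ---------------------------------------------------------

    def _validate_input(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        if X.ndim != 3:
            raise ValueError(f"expected (n, C, T) input, got shape {X.shape}")
        if fitted and X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"segments of shape {X.shape[1:]} do not match the fitted "
                f"input shape {self.input_shape_}"
            )
        return X

    def _forward_batches(self, X, train=False, rng=None, batch=256):
        probs, feats = [], []
        Xb = np.asarray(X)[:, None].astype(np.float32)
        for start in range(0, Xb.shape[0], batch):
            logits, f = self.model_.forward(Xb[start:start + batch],
                                            train=train, rng=rng,
                                            tap=self._tap)
            probs.append(nn.softmax(logits.astype(np.float64)))
            feats.append(f.copy())
        return np.concatenate(probs), np.concatenate(feats)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._validate_input(np.asarray(X), fitted=True)
        probs, _ = self._forward_batches(X)
        return probs

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)  # tie -> 1

    def transform(self, X):
        """Flattened final-conv-layer features, one row per segment."""
        check_is_fitted(self, "model_")
        X = self._validate_input(np.asarray(X), fitted=True)
        _, feats = self._forward_batches(X)
        return feats

    def predict_with_features(self, X):
        """One forward pass serving both prediction and feature extraction."""
        check_is_fitted(self, "model_")
        X = self._validate_input(np.asarray(X), fitted=True)
        probs, feats = self._forward_batches(X)
        labels = (probs[:, 1] >= 0.5).astype(int)
        return labels, probs, feats

    def save(self, path) -> None:
        """Serialize the fitted classifier (parameters + config) to a file."""
        import joblib

        check_is_fitted(self, "model_")
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "CNNSegmentClassifier":
        import joblib

        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a {cls.__name__}")
        return obj

    def mc_dropout_proba(self, X, passes: int = 30, seed: int = 0):
        """Class probabilities from ``passes`` stochastic dropout passes.

        The convolutional stack is deterministic (dropout sits in front of
        the fully connected head), so its features are computed once and
        only the head is resampled.  Returns shape ``(passes, n, 2)``.
        """
        check_is_fitted(self, "model_")
        if passes < 2:
            raise ValueError("Monte Carlo dropout needs at least 2 passes")
        X = self._validate_input(np.asarray(X), fitted=True)
        rng = np.random.default_rng(seed)
        _, feats = self._forward_batches(X)
        head = self.model_.layers[self._tap + 1:]
        out = []
        for _ in range(passes):
            h = feats
            for layer in head:
                h = layer.forward(h, train=True, rng=rng)
            out.append(nn.softmax(h.astype(np.float64)))
        return np.stack(out)


def predict_segments(classifier: CNNSegmentClassifier, X
                     ) -> list[SegmentPrediction]:
    """Per-segment predictions with attached features, batch order preserved."""
    labels, probs, feats = classifier.predict_with_features(X)
    return [SegmentPrediction(int(l), float(p), f)
            for l, p, f in zip(labels, probs[:, 1], feats)]


def lopo_folds(patient_ids) -> list[tuple[list, object]]:
    """Leave-one-patient-out folds: one (train_ids, test_id) pair per patient."""
    ids = list(dict.fromkeys(patient_ids))  # stable unique
    if len(ids) < 2:
        raise ValueError("LOPO cross-validation needs at least 2 patients")
    return [([p for p in ids if p != test], test) for test in ids]


def classification_metrics(labels, predictions, probs=None) -> dict:
    """Standard per-patient detection metrics.

    Metrics undefined for a degenerate label vector (single class) are
    reported as ``nan`` rather than 0.
    """
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions length mismatch")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    n = y.size
    out = {"accuracy": (tp + tn) / n if n else np.nan}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else np.nan
    out["specificity"] = tn / (tn + fp) if (tn + fp) else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    rec = out["sensitivity"]
    if tp == 0:
        out["f1"] = 0.0 if (fp + fn) > 0 and (tp + fn) > 0 else np.nan
    else:
        out["f1"] = 2 * prec * rec / (prec + rec)
    if probs is not None and len(set(y.tolist())) == 2:
        out["auc"] = float(roc_auc_score(y, np.asarray(probs)))
    else:
        out["auc"] = np.nan
    return out
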