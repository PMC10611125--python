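"""Comparison uncertainty estimators, each aggregated to a patient score.

Three standard techniques serve as baselines for the grouped detector:

* **SoftMax confidence** — per segment ``u = 2 (1 - max class probability)``,
  which maps the two-class probability range [0.5, 1] onto [0, 1];
* **Monte Carlo dropout** — dropout kept active over repeated stochastic
  forward passes; per segment the normalized predictive entropy (entropy of
  the mean class-1 probability, in bits) is the uncertainty;
* **single Deep SVDD** — one detector fitted on the *undivided* training
  feature set; the patient score is the mean binary OOD flag.

Patient scores are segment means in [0, 1].  SoftMax and MC-dropout scores
tend to cluster near 0 (overconfident networks), so cohort-level min-max
rescaling is provided to make the methods comparable; rescaling preserves
patient ranking and therefore correlation-based comparisons.
"""

from __future__ import annotations

import numpy as np

from .svdd import DeepSVDD

__all__ = [
    "softmax_uncertainty",
    "mc_dropout_uncertainty",
    "single_svdd_uncertainty",
    "minmax_rescale",
]


def softmax_uncertainty(classifier, segments) -> float:
    """Mean per-segment SoftMax uncertainty for one patient's segments."""
    X = np.asarray(segments)
    if X.shape[0] == 0:
        raise ValueError("no segments supplied")
    probs = classifier.predict_proba(X)
    u = 2.0 * (1.0 - probs.max(axis=1))
    return float(u.mean())


def _binary_entropy_bits(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def mc_dropout_uncertainty(classifier, segments, passes: int = 30,
                           seed: int = 0) -> float:
    """Mean normalized predictive entropy across stochastic dropout passes."""
    X = np.asarray(segments)
    if X.shape[0] == 0:
        raise ValueError("no segments supplied")
    if passes < 2:
        raise ValueError("Monte Carlo dropout needs at least 2 passes")
    probs = classifier.mc_dropout_proba(X, passes=passes, seed=seed)
    mean_p1 = probs[:, :, 1].mean(axis=0)
    return float(_binary_entropy_bits(mean_p1).mean())


def single_svdd_uncertainty(svdd: DeepSVDD, features) -> float:
    """Mean OOD flag of a single whole-training-set detector."""
    feats = np.asarray(features)
    if feats.shape[0] == 0:
        raise ValueError("no segments supplied")
    return float(svdd.predict(feats).mean())


def minmax_rescale(scores) -> np.ndarray:
    """Affine map of a per-patient score vector onto [0, 1].

    The cohort maximum maps to 1.  A constant vector maps to all zeros
    (degenerate rule: no patient stands out).
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("min-max rescaling needs at least 2 patients")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-15:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)
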