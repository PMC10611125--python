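"""Evaluation of patient-level uncertainty methods against detector skill.

The ground truth for "should the model have been uncertain about this
patient?" is derived from the detector's own held-out F1 score: a patient is
*confident* (truth 0) iff their F1 strictly exceeds a threshold (0.5 by
default; 0.7 and 0.8 model progressively more conservative clinical use).
An uncertainty method is then judged two ways:

* the Pearson correlation between its patient scores and the per-patient F1
  (an effective method is strongly negatively correlated);
* patient-level classification metrics at a 0.5 score threshold, with
  "uncertain" as the positive class and rank-AUC over the continuous scores.

A reference per-patient performance table of the bundled CNN architecture
on the 23-patient CHB-MIT corpus ships with the package; its aggregate row
(mean and sample SD per column) is reproduced by :func:`summarize_cohort`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "truth_labels",
    "pearson_r",
    "patient_classification_metrics",
    "summarize_cohort",
    "load_reference_table",
    "evaluate_methods",
]


def truth_labels(f1_per_patient, f1_threshold: float = 0.5) -> np.ndarray:
    """1 = the model should be uncertain about this patient.

    Confident (0) requires the F1 to *strictly exceed* the threshold;
    equality counts as uncertain.
    """
    f1 = np.asarray(f1_per_patient, dtype=float)
    if np.any((f1 < 0) | (f1 > 1)):
        raise ValueError("F1 values must lie in [0, 1]")
    return (~(f1 > f1_threshold)).astype(int)


def pearson_r(x, y) -> float:
    """Product-moment correlation; ``nan`` for constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def patient_classification_metrics(scores, truth,
                                   score_threshold: float = 0.5) -> dict:
    """Uncertain-vs-confident patient classification at a score threshold.

    A patient is predicted uncertain iff ``score >= score_threshold`` (the
    boundary resolves to uncertain).  Positive class = uncertain.  Metrics
    undefined under a single-class truth vector are ``nan``.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and truth length mismatch")
    pred = (s >= score_threshold).astype(int)
    tp = int(np.sum((t == 1) & (pred == 1)))
    tn = int(np.sum((t == 0) & (pred == 0)))
    fp = int(np.sum((t == 0) & (pred == 1)))
    fn = int(np.sum((t == 1) & (pred == 0)))
    out = {"accuracy": (tp + tn) / t.size if t.size else np.nan}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else np.nan
    out["specificity"] = tn / (tn + fp) if (tn + fp) else np.nan
    out["auc"] = (float(roc_auc_score(t, s))
                  if len(set(t.tolist())) == 2 else np.nan)
    return out


def summarize_cohort(per_patient: pd.DataFrame,
                     decimals: int = 2) -> pd.DataFrame:
    """Column means and sample (n-1) standard deviations.

    Returns a two-row frame (``mean``, ``sd``) rounded to ``decimals``.
    """
    if len(per_patient) < 2:
        raise ValueError("cohort summary needs at least 2 patients")
    numeric = per_patient.select_dtypes(include=[np.number])
    out = pd.DataFrame({
        "mean": numeric.mean(),
        "sd": numeric.std(ddof=1),
    }).T
    return out.round(decimals)


def load_reference_table() -> pd.DataFrame:
    """Bundled per-patient CHB-MIT performance of the reference CNN."""
    with resources.files("szuq.data").joinpath(
            "chbmit_cnn_reference.csv").open() as fh:
        return pd.read_csv(fh)


def evaluate_methods(results: pd.DataFrame, f1_threshold: float = 0.5,
                     score_threshold: float = 0.5,
                     rescaled_methods=("softmax", "mc_dropout")) -> dict:
    """Evaluate every uncertainty method in a per-patient results frame.

    ``results`` must contain columns ``patient``, ``f1`` and one score
    column per method.  Methods in ``rescaled_methods`` are cohort min-max
    rescaled before thresholded classification (correlation and AUC are
    affine-invariant, so they use the raw scores).
    """
    from .baselines import minmax_rescale

    truth = truth_labels(results["f1"].to_numpy(), f1_threshold)
    report: dict = {"f1_threshold": f1_threshold, "truth": truth.tolist(),
                    "methods": {}}
    detection_cols = {"patient", "f1", "accuracy", "sensitivity",
                      "specificity", "auc"}
    method_cols = [c for c in results.columns
                   if c not in detection_cols and
                   np.issubdtype(results[c].dtype, np.number)]
    for method in method_cols:
        raw = results[method].to_numpy(dtype=float)
        scored = (minmax_rescale(raw) if method in rescaled_methods else raw)
        try:
            r = pearson_r(raw, results["f1"].to_numpy())
        except ValueError:  # fewer than 3 patients
            r = float("nan")
        entry = {"pearson_r": r}
        entry.update(patient_classification_metrics(scored, truth,
                                                    score_threshold))
        report["methods"][method] = entry
    return report
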