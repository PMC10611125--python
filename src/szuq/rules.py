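"""Rule-based per-segment confidence decisions and patient-level aggregation.

Each one-second segment carries the classifier's binary prediction plus four
binary out-of-distribution flags, one per confusion-group detector.  The
rule declares the prediction *confident* only when the flags are coherent
with it:

* prediction 0 (non-seizure) is confident iff the segment looks
  in-distribution to at least one non-seizure group (TN or FN) **and**
  out-of-distribution to both seizure groups (TP and FP);
* prediction 1 (seizure) is confident iff the segment looks in-distribution
  to at least one seizure group (TP or FP) **and** out-of-distribution to
  both non-seizure groups (TN and FN).

Every other flag combination is *uncertain*.  Of the 32 possible
(prediction, flags) combinations exactly 6 are confident, 3 per prediction
value.  A patient's uncertainty score is the mean of their segments'
uncertainty bits, in [0, 1]; a score at or above 0.5 classifies the patient
as one the model is uncertain about (the 0.5 boundary is resolved toward
uncertainty — the conservative branch for a safety tool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .svdd import GROUPS

__all__ = [
    "GroupFlags",
    "SegmentVerdict",
    "PatientUncertainty",
    "rule_decide",
    "score_patient",
    "estimate_patient",
]


@dataclass(frozen=True)
class GroupFlags:
    """Per-group OOD flags; 0 = in-distribution, 1 = out-of-distribution."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for g in GROUPS:
            if getattr(self, g) not in (0, 1):
                raise ValueError(f"flag {g} must be 0 or 1")

    @classmethod
    def from_array(cls, row) -> "GroupFlags":
        """Build from a length-4 array ordered (tp, fp, tn, fn)."""
        tp, fp, tn, fn = (int(v) for v in row)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class SegmentVerdict:
    """One segment's prediction, flags, and confidence decision."""

    prediction: int
    flags: GroupFlags
    uncertain: int  # 0 confident, 1 uncertain


@dataclass(frozen=True)
class PatientUncertainty:
    """Aggregated patient-level uncertainty."""

    patient_id: str
    score: float          # mean of per-segment uncertainty bits
    n_segments: int
    decision: str         # "confident" | "uncertain"


def rule_decide(prediction: int, flags: GroupFlags) -> int:
    """Confidence decision for one segment: 0 confident, 1 uncertain."""
    if prediction not in (0, 1):
        raise ValueError("prediction must be 0 or 1")
    if prediction == 0:
        confident = (flags.fn == 0 or flags.tn == 0) and \
            flags.fp == 1 and flags.tp == 1
    else:
        confident = (flags.fp == 0 or flags.tp == 0) and \
            flags.tn == 1 and flags.fn == 1
    return 0 if confident else 1


def score_patient(verdicts: list[SegmentVerdict],
                  patient_id: str = "") -> PatientUncertainty:
    """Average per-segment uncertainty bits into a patient-level score."""
    if not verdicts:
        raise ValueError("cannot score a patient with no segments")
    bits = np.array([v.uncertain for v in verdicts], dtype=float)
    score = float(bits.mean())
    return PatientUncertainty(
        patient_id=patient_id,
        score=score,
        n_segments=len(verdicts),
        decision="uncertain" if score >= 0.5 else "confident",
    )


def estimate_patient(classifier, grouped_model, segments,
                     patient_id: str = "") -> tuple[PatientUncertainty,
                                                    list[SegmentVerdict]]:
    """Full per-patient pipeline: predict, flag, decide, aggregate.

    ``segments`` is an ``(n, C, T)`` array of preprocessed windows from one
    patient.  A single forward pass serves both the class prediction and
    the feature vector consumed by the group detectors.
    """
    X = np.asarray(segments)
    if X.shape[0] == 0:
        raise ValueError("no segments supplied")
    labels, _, feats = classifier.predict_with_features(X)
    flag_rows = grouped_model.flags(feats)
    verdicts = []
    for pred, row in zip(labels, flag_rows):
        flags = GroupFlags.from_array(row)
        verdicts.append(SegmentVerdict(int(pred), flags,
                                       rule_decide(int(pred), flags)))
    return score_patient(verdicts, patient_id), verdicts
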