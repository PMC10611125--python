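import numpy as np
import pytest

from szuq import PatientProfile, Recording, SeizureAnnotation, generate_recording
from szuq.classifier import CNNSegmentClassifier


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def short_recording():
    """10 s, 2-channel noise recording with one 2 s seizure annotation."""
    sig = np.random.default_rng(0).standard_normal((2, 2560)) * 20.0
    return Recording(
        patient_id="p00", channel_labels=["C1", "C2"], sample_rate_hz=256.0,
        signal=sig, annotations=[SeizureAnnotation(3.0, 5.0)],
        recording_id="p00_r01",
    )


@pytest.fixture(scope="session")
def tiny_classifier():
    """A small CNN fitted on a linearly separable toy set (amortized)."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((64, 4, 64)).astype(np.float32)
    y = np.array([0, 1] * 32)
    X[y == 1] += 1.5
    clf = CNNSegmentClassifier(
        filters=(4, 4, 4, 4), kernels=((3, 2), (3, 1), (3, 1), (3, 1)),
        fc_width=16, dropout=0.25, lr=1e-2, epochs=30, seed=0,
    ).fit(X, y)
    return clf, X, y
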