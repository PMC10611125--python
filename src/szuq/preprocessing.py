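"""Turn annotated recordings into labeled one-second training segments.

Pipeline order is fixed: channel selection -> DC removal + zero-phase FIR
bandpass (1-60 Hz) -> per-channel min-max normalization to [0, 1] ->
sliding-window segmentation -> class rebalancing.  Filtering precedes
normalization because filtering after a [0, 1] rescale would destroy the
bounded range the classifier expects.

Segmentation conventions:

* ictal intervals are tiled with ``window_s`` windows at stride
  ``seizure_step_s`` (default 0.5 s, i.e. 50% overlap, which roughly doubles
  the number of seizure segments from the same ictal time);
* the ``peri_s`` (default 30 s) before each onset and after each offset are
  tiled with non-overlapping windows phase-tagged ``preictal`` /
  ``postictal`` but labeled non-seizure;
* everything else is tiled with non-overlapping ``interictal`` windows;
* partial trailing windows are discarded; no window straddles a phase
  boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "Segment",
    "SegmentDataset",
    "bandpass_and_dc_remove",
    "normalize01",
    "segment_recording",
    "rebalance",
    "preprocess_recording",
]

PHASES = ("interictal", "preictal", "ictal", "postictal")


@dataclass
class Segment:
    """One fixed-length multichannel window, the atomic classification unit."""

    patient_id: str
    recording_id: str
    start_s: float
    data: np.ndarray          # (C, T), values in [0, 1] after normalization
    label: int                # 1 iff ictal
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if (self.label == 1) != (self.phase == "ictal"):
            raise ValueError("label 1 <=> phase ictal")


@dataclass
class SegmentDataset:
    """A list of segments plus provenance of how they were produced."""

    segments: list[Segment]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)

    def stack(self) -> np.ndarray:
        """Segments as one (n, C, T) float32 array."""
        return np.stack([s.data for s in self.segments]).astype(np.float32)

    def subset(self, idx) -> "SegmentDataset":
        segs = [self.segments[i] for i in idx]
        return SegmentDataset(segs, dict(self.provenance))


def bandpass_and_dc_remove(
    recording: Recording,
    low_hz: float = 1.0,
    high_hz: float = 60.0,
    numtaps: int = 513,
) -> Recording:
    """Remove per-channel DC then apply a zero-phase FIR bandpass.

    The filter is a Hamming-windowed FIR design applied forward-backward
    (zero phase), so annotations stay aligned with the signal.
    """
    rate = recording.sample_rate_hz
    if high_hz >= rate / 2:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below Nyquist {rate / 2} Hz"
        )
    if numtaps % 2 == 0:
        raise ValueError("numtaps must be odd")
    max_taps = max(3, (recording.n_samples - 1) // 3)
    taps = sps.firwin(
        min(numtaps, max_taps if max_taps % 2 else max_taps - 1),
        [low_hz, high_hz], pass_zero=False, fs=rate,
    )
    x = recording.signal - recording.signal.mean(axis=1, keepdims=True)
    filtered = sps.filtfilt(taps, [1.0], x, axis=1)
    return recording.with_signal(filtered)


def normalize01(recording: Recording, scope: str = "channel") -> Recording:
    """Min-max rescale the signal to [0, 1].

    ``scope='channel'`` (default) rescales each channel over the whole
    recording so every channel attains both 0 and 1; ``scope='recording'``
    uses a single global range.
    """
    x = recording.signal.astype(np.float64)
    if scope == "channel":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        flat = np.where((hi - lo).ravel() < 1e-12)[0]
        if flat.size:
            names = ", ".join(recording.channel_labels[i] for i in flat)
            raise ValueError(f"constant channel(s) cannot be normalized: {names}")
    elif scope == "recording":
        lo, hi = x.min(), x.max()
        if hi - lo < 1e-12:
            raise ValueError("constant recording cannot be normalized")
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    return recording.with_signal((x - lo) / (hi - lo))


def _tile(start: float, stop: float, window: float, step: float) -> list[float]:
    """Window start times in [start, stop - window], inclusive, at ``step``."""
    out = []
    s = start
    while s + window <= stop + 1e-9:
        out.append(round(s, 6))
        s += step
    return out


def segment_recording(
    recording: Recording,
    window_s: float = 1.0,
    seizure_step_s: float = 0.5,
    peri_s: float = 30.0,
) -> list[Segment]:
    """Slice a preprocessed recording into phase-tagged labeled windows.

    Peri-ictal spans are truncated at the recording edges and at adjacent
    seizures (a postictal span ends where the next seizure starts; a
    preictal span starts no earlier than the previous postictal span ends).
    Preictal windows are tiled backward from the onset and postictal windows
    forward from the offset, so they stay flush with the seizure.
    """
    rate = recording.sample_rate_hz
    if abs(window_s * rate - round(window_s * rate)) > 1e-9:
        raise ValueError("window_s times sample rate must be an integer")
    dur = recording.duration_s
    if window_s > dur + 1e-9:
        raise ValueError("window longer than recording")

    anns = recording.annotations
    spans: list[tuple[float, float, str]] = []  # (start, stop, phase)
    for i, ann in enumerate(anns):
        spans.append((ann.onset_s, ann.offset_s, "ictal"))
        post_end = min(ann.offset_s + peri_s, dur)
        if i + 1 < len(anns):
            post_end = min(post_end, anns[i + 1].onset_s)
        if post_end > ann.offset_s:
            spans.append((ann.offset_s, post_end, "postictal"))
    for i, ann in enumerate(anns):
        pre_start = max(ann.onset_s - peri_s, 0.0)
        if i > 0:  # do not reach into the previous seizure's postictal span
            prev_post_end = min(anns[i - 1].offset_s + peri_s, ann.onset_s)
            pre_start = max(pre_start, prev_post_end)
        if ann.onset_s > pre_start:
            spans.append((pre_start, ann.onset_s, "preictal"))
    spans.sort()

    # interictal = complement of ictal + peri spans
    inter: list[tuple[float, float, str]] = []
    cursor = 0.0
    for start, stop, _ in spans:
        if start > cursor + 1e-9:
            inter.append((cursor, start, "interictal"))
        cursor = max(cursor, stop)
    if dur > cursor + 1e-9:
        inter.append((cursor, dur, "interictal"))

    segments: list[Segment] = []

    def emit(start_s: float, phase: str) -> None:
        i0 = int(round(start_s * rate))
        i1 = i0 + int(round(window_s * rate))
        label = 1 if phase == "ictal" else 0
        segments.append(Segment(
            patient_id=recording.patient_id,
            recording_id=recording.recording_id,
            start_s=start_s,
            data=recording.signal[:, i0:i1],
            label=label,
            phase=phase,
        ))

    for start, stop, phase in spans + inter:
        if phase == "ictal":
            starts = _tile(start, stop, window_s, seizure_step_s)
        elif phase == "preictal":
            # tile backward from the onset so windows stay flush with it
            n = int((stop - start + 1e-9) // window_s)
            starts = [round(stop - (k + 1) * window_s, 6) for k in range(n)][::-1]
        else:
            starts = _tile(start, stop, window_s, window_s)
        for s in starts:
            emit(s, phase)

    segments.sort(key=lambda s: (s.start_s, -s.label))
    return segments


def rebalance(dataset: SegmentDataset, ratio: float = 5.0,
              seed: int = 0) -> SegmentDataset:
    """Subsample non-seizure segments to at most ``ratio`` per seizure segment.

    All seizure segments are kept; non-seizure segments are drawn uniformly
    without replacement.  Segment contents are never modified.
    """
    labels = dataset.labels
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    if pos.size == 0:
        raise ValueError("rebalance requires at least one seizure segment")
    n_keep = min(neg.size, int(ratio * pos.size))
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg, size=n_keep, replace=False) if n_keep else []
    idx = np.sort(np.concatenate([pos, np.asarray(kept_neg, dtype=int)]))
    out = dataset.subset(idx)
    out.provenance["rebalance"] = {"ratio": ratio, "seed": seed,
                                   "n_pos": int(pos.size), "n_neg_kept": n_keep}
    return out


def preprocess_recording(
    recording: Recording,
    canonical_channels=None,
    low_hz: float = 1.0,
    high_hz: float = 60.0,
    numtaps: int = 513,
    normalize_scope: str = "channel",
    window_s: float = 1.0,
    seizure_step_s: float = 0.5,
    peri_s: float = 30.0,
) -> list[Segment]:
    """Full per-recording pipeline: select -> filter -> normalize -> segment."""
    from .io import select_channels

    rec = recording
    if canonical_channels is not None:
        rec = select_channels(rec, canonical_channels)
    rec = bandpass_and_dc_remove(rec, low_hz, high_hz, numtaps)
    rec = normalize01(rec, scope=normalize_scope)
    return segment_recording(rec, window_s, seizure_step_s, peri_s)
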