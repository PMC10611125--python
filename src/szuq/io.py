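"""Domain types and I/O for multichannel EEG recordings.

A :class:`Recording` bundles one patient's multichannel scalp EEG signal
(microvolts, channels x samples) with its sample rate and seizure
annotations.  Signals travel as EDF files; annotations travel either as the
CHB-MIT plain-text summary dialect or as a small CSV dialect with header
``recording,onset_s,offset_s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SeizureAnnotation",
    "Recording",
    "CHB_MIT_22_CHANNELS",
    "read_edf",
    "write_edf",
    "read_annotations",
    "select_channels",
]

#: Default canonical montage: the 22 longitudinal-bipolar channel labels shared
#: by the CHB-MIT recordings (duplicates and non-EEG channels excluded).
CHB_MIT_22_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8",
)


@dataclass(frozen=True)
class SeizureAnnotation:
    """One seizure event, in seconds from recording start."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"invalid seizure annotation: onset {self.onset_s} must be "
                f"non-negative and strictly before offset {self.offset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Recording:
    """One patient's multichannel EEG signal plus seizure annotations.

    Parameters
    ----------
    patient_id : str
        Opaque patient label.
    channel_labels : list of str
        Ordered channel names; must match the first axis of ``signal``.
    sample_rate_hz : float
        Samples per second per channel (CHB-MIT uses 256 Hz).
    signal : ndarray, shape (n_channels, n_samples)
        Channel-major signal, microvolts when raw.
    annotations : list of SeizureAnnotation
        Non-overlapping seizure events sorted by onset.
    recording_id : str
        Identifier distinguishing multiple recordings of one patient.
    """

    patient_id: str
    channel_labels: list[str]
    sample_rate_hz: float
    signal: np.ndarray
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels but signal has "
                f"{self.signal.shape[0]} rows"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self._validate_annotations()

    def _validate_annotations(self) -> None:
        dur = self.duration_s
        prev_off = 0.0
        for ann in self.annotations:
            if ann.onset_s < prev_off:
                raise ValueError(
                    "annotations must be sorted by onset and non-overlapping"
                )
            if ann.offset_s > dur + 1e-9:
                raise ValueError(
                    f"annotation offset {ann.offset_s} s exceeds recording "
                    f"duration {dur} s"
                )
            prev_off = ann.offset_s

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def with_signal(self, signal: np.ndarray) -> "Recording":
        """Copy of this recording with ``signal`` replaced."""
        return replace(self, signal=signal)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (annotations left empty).

    Signals are returned in microvolts.  The patient id defaults to the file
    stem up to the first underscore (CHB-MIT convention ``chb01_03.edf``),
    the recording id to the full stem.
    """
    import mne

    path = Path(path)
    if not path.is_file():
        raise IOError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for corrupt files
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    if len(raw.ch_names) < 1:
        raise IOError(f"EDF file {path} contains no signal channels")
    rates = set(raw._raw_extras[0].get("n_samps", [])) if raw._raw_extras else set()
    if len(rates) > 1:
        raise ValueError(
            f"EDF file {path} mixes per-channel sample rates; unsupported"
        )
    data = raw.get_data(units="uV")
    stem = path.stem
    return Recording(
        patient_id=stem.split("_")[0],
        channel_labels=list(raw.ch_names),
        sample_rate_hz=float(raw.info["sfreq"]),
        signal=np.ascontiguousarray(data),
        recording_id=stem,
    )


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to a plain EDF file.

    Each channel is quantized to 16 bits over its own physical range, the
    standard EDF encoding, so values round-trip to within
    ``(max - min) / 65535`` per channel.  The recording must contain an
    integer number of one-second data records.
    """
    path = Path(path)
    rate = recording.sample_rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("write_edf requires an integer sample rate")
    rate = int(round(rate))
    n_records, rem = divmod(recording.n_samples, rate)
    if rem:
        raise ValueError("write_edf requires an integer number of seconds")
    ns = recording.n_channels

    def _pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    sig = np.asarray(recording.signal, dtype=np.float64)
    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    header = b"".join([
        _pad("0", 8),
        _pad(f"X X X {recording.patient_id or 'X'}", 80),
        _pad(f"Startdate X X X X {recording.recording_id or 'X'}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),          # record duration, seconds
        _pad(str(ns), 4),
    ])
    fields = [
        ("".join(_pad(lbl, 16).decode() for lbl in recording.channel_labels)),
        ("".join(_pad("", 80).decode() for _ in range(ns))),
        ("".join(_pad("uV", 8).decode() for _ in range(ns))),
        ("".join(_pad(f"{v:.6g}"[:8], 8).decode() for v in phys_min)),
        ("".join(_pad(f"{v:.6g}"[:8], 8).decode() for v in phys_max)),
        ("".join(_pad("-32768", 8).decode() for _ in range(ns))),
        ("".join(_pad("32767", 8).decode() for _ in range(ns))),
        ("".join(_pad("", 80).decode() for _ in range(ns))),
        ("".join(_pad(str(rate), 8).decode() for _ in range(ns))),
        ("".join(_pad("", 32).decode() for _ in range(ns))),
    ]
    header += "".join(fields).encode("ascii")

    scale = (phys_max - phys_min) / 65535.0
    digital = np.round((sig - phys_min[:, None]) / scale[:, None]) - 32768
    digital = np.clip(digital, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * rate:(rec + 1) * rate]
            fh.write(chunk.tobytes())  # channel-major within a record


def _parse_csv_annotations(path: Path) -> dict[str, list[SeizureAnnotation]]:
    out: dict[str, list[SeizureAnnotation]] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "recording,onset_s,offset_s":
            raise ValueError(
                f"{path}: expected header 'recording,onset_s,offset_s', "
                f"got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            rec, onset, offset = parts
            try:
                ann = SeizureAnnotation(float(onset), float(offset))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(rec, []).append(ann)
    return out


_SUMMARY_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.IGNORECASE)
_SUMMARY_START_RE = re.compile(
    r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec", re.IGNORECASE
)
_SUMMARY_END_RE = re.compile(
    r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec", re.IGNORECASE
)


def _parse_summary_annotations(path: Path) -> dict[str, list[SeizureAnnotation]]:
    """Parse the CHB-MIT ``*-summary.txt`` dialect.

    Blocks look like::

        File Name: chb01_03.edf
        Number of Seizures in File: 1
        Seizure Start Time: 2996 seconds
        Seizure End Time: 3036 seconds
    """
    out: dict[str, list[SeizureAnnotation]] = {}
    current: str | None = None
    pending_start: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            m = _SUMMARY_FILE_RE.match(line)
            if m:
                current = Path(m.group(1)).stem
                out.setdefault(current, [])
                pending_start = None
                continue
            m = _SUMMARY_START_RE.match(line)
            if m:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: seizure before any file")
                pending_start = float(m.group(1))
                continue
            m = _SUMMARY_END_RE.match(line)
            if m:
                if current is None or pending_start is None:
                    raise ValueError(f"{path}:{lineno}: end time without start")
                try:
                    ann = SeizureAnnotation(pending_start, float(m.group(1)))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                out[current].append(ann)
                pending_start = None
    return out


def read_annotations(
    path: str | Path, dialect: str = "csv"
) -> dict[str, list[SeizureAnnotation]]:
    """Read seizure annotations, keyed by recording name.

    Parameters
    ----------
    path : path
        Annotation file.
    dialect : {"csv", "chbmit_summary"}
        ``csv`` expects header ``recording,onset_s,offset_s``;
        ``chbmit_summary`` parses the CHB-MIT summary-text blocks.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"annotation file not found: {path}")
    if dialect == "csv":
        out = _parse_csv_annotations(path)
    elif dialect == "chbmit_summary":
        out = _parse_summary_annotations(path)
    else:
        raise ValueError(
            f"unknown annotation dialect {dialect!r}; "
            "expected 'csv' or 'chbmit_summary'"
        )
    for anns in out.values():
        anns.sort(key=lambda a: a.onset_s)
    return out


def select_channels(
    recording: Recording,
    canonical: tuple[str, ...] | list[str] = CHB_MIT_22_CHANNELS,
) -> Recording:
    """Restrict a recording to a canonical ordered channel set.

    The first occurrence wins when a label is duplicated; channels not in
    ``canonical`` (non-EEG, patient-specific extras) are dropped.  Raises
    if any canonical channel is missing.
    """
    labels = [lbl.strip().upper() for lbl in recording.channel_labels]
    wanted = [c.strip().upper() for c in canonical]
    missing = [c for c in wanted if c not in labels]
    if missing:
        raise ValueError(
            f"recording {recording.recording_id or recording.patient_id} is "
            f"missing canonical channels: {', '.join(missing)}"
        )
    idx = [labels.index(c) for c in wanted]  # first occurrence wins
    return replace(
        recording,
        channel_labels=list(canonical),
        signal=recording.signal[idx],
    )
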