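"""Seeded synthetic multi-patient EEG cohorts with seizure morphology families.

The generator emulates the structure a seizure-detection pipeline depends on:
multichannel fixed-rate recordings dominated by 1/f background activity, with
rare annotated ictal intervals carrying rhythmic spike-wave bursts.  Each
patient belongs to a *morphology family* — a (burst frequency, waveform shape,
amplitude ratio) triple — and a designated subset of "out-of-distribution"
patients draws its seizures from a family no other patient uses.  That is the
property a patient-level uncertainty method must detect: a detector trained
without a family should be uncertain about patients who have it.

Background is 1/f-filtered Gaussian noise with shared low-rank spatial mixing
(scalp channels are strongly correlated); it makes no attempt at physiological
realism (no eye-blink or muscle artifacts, no sleep staging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording, SeizureAnnotation

__all__ = [
    "SeizureFamily",
    "FAMILIES",
    "PatientProfile",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
]

#: Minimum gap between consecutive seizures so 30 s peri-ictal spans
#: never overlap.
MIN_SEIZURE_GAP_S = 61.0


@dataclass(frozen=True)
class SeizureFamily:
    """A seizure morphology family: what the ictal burst looks like."""

    name: str
    spike_wave_hz: float      # rhythmic burst frequency
    shape: str                # {"spike_wave", "rhythmic", "polyspike"}
    amp_ratio: float          # ictal/background amplitude ratio, > 1


#: Built-in families.  The in-distribution defaults are classic low-frequency
#: high-amplitude spike-wave discharges; the out-of-distribution family is a
#: faster, lower-amplitude rhythmic discharge that a detector trained on the
#: others tends to miss.
FAMILIES: dict[str, SeizureFamily] = {
    "spike_wave_3hz": SeizureFamily("spike_wave_3hz", 3.0, "spike_wave", 4.0),
    "spike_wave_4hz": SeizureFamily("spike_wave_4hz", 4.0, "spike_wave", 3.5),
    "polyspike_5hz": SeizureFamily("polyspike_5hz", 5.0, "polyspike", 3.5),
    "rhythmic_9hz": SeizureFamily("rhythmic_9hz", 9.0, "narrowband", 1.02),
}


@dataclass
class PatientProfile:
    """Generation parameters for one synthetic patient.

    Defaults give a 600 s recording with two 6 s seizures (2% ictal time,
    mirroring the rarity of ictal activity in long-term clinical EEG).
    """

    patient_id: str
    seizure_family: str = "spike_wave_3hz"
    background_amp_uv: float = 40.0
    noise_exponent: float = 1.0
    n_seizures: int = 2
    seizure_duration_s: float = 6.0
    recording_duration_s: float = 600.0
    seed: int = 0
    spike_wave_hz: float | None = None     # family override
    seizure_amp_ratio: float | None = None  # family override
    #: Seed of the cohort-shared spatial mixing matrix.  Scalp channels are
    #: correlated the same way across people, so the mixing structure is a
    #: cohort property; per-patient deviation is controlled by spatial_jitter.
    mixing_seed: int = 0
    spatial_jitter: float = 0.04
    #: Stationary log-amplitude modulation of the background (vigilance-like
    #: slow waxing and waning): Ornstein-Uhlenbeck process with this standard
    #: deviation and a 20 s correlation time.  0 disables it.
    am_sigma: float = 0.25
    am_tau_s: float = 20.0
    #: Interictal epileptiform discharges: brief isolated bursts of the
    #: patient's own seizure-family waveform scattered through background
    #: (not annotated — clinical annotations mark seizures only).
    interictal_spikes_per_min: float = 10.0
    interictal_spike_duration_s: float = 0.4
    interictal_spike_amp_ratio: float = 2.0

    def __post_init__(self) -> None:
        fam = FAMILIES.get(self.seizure_family)
        if fam is None:
            raise ValueError(f"unknown seizure family {self.seizure_family!r}")
        if self.spike_wave_hz is None:
            self.spike_wave_hz = fam.spike_wave_hz
        if self.seizure_amp_ratio is None:
            self.seizure_amp_ratio = fam.amp_ratio
        if self.seizure_amp_ratio <= 1:
            raise ValueError("seizure_amp_ratio must exceed 1")
        if self.n_seizures < 0 or self.seizure_duration_s <= 0:
            raise ValueError("invalid seizure count or duration")
        span = self.n_seizures * self.seizure_duration_s
        if span >= self.recording_duration_s:
            raise ValueError("total ictal time must be below recording duration")
        need = (
            self.n_seizures * (self.seizure_duration_s + MIN_SEIZURE_GAP_S)
            + MIN_SEIZURE_GAP_S
        )
        if self.n_seizures and need > self.recording_duration_s:
            raise ValueError(
                f"recording of {self.recording_duration_s} s cannot hold "
                f"{self.n_seizures} seizures separated by {MIN_SEIZURE_GAP_S} s"
            )


@dataclass
class CohortSpec:
    """A multi-patient cohort with a designated out-of-distribution subset.

    In-distribution patients cycle through ``id_families`` (each family is
    shared by at least two patients for the default sizes); patients listed
    in ``ood_patient_ids`` use ``ood_family``, which must not occur among
    the in-distribution assignments.
    """

    n_patients: int = 8
    ood_patient_ids: tuple[str, ...] = ("p07", "p08")
    id_families: tuple[str, ...] = ("spike_wave_3hz", "polyspike_5hz")
    ood_family: str = "rhythmic_9hz"
    recording_duration_s: float = 600.0
    n_seizures: int = 2
    seizure_duration_s: float = 6.0
    n_channels: int = 22
    sample_rate_hz: float = 256.0
    seed: int = 0

    def patient_ids(self) -> list[str]:
        return [f"p{i + 1:02d}" for i in range(self.n_patients)]

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        unknown = set(self.ood_patient_ids) - set(self.patient_ids())
        if unknown:
            raise ValueError(f"ood_patient_ids not in cohort: {sorted(unknown)}")
        if self.ood_family in self.id_families:
            raise ValueError("ood_family must differ from every shared family")


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                exponent: float) -> np.ndarray:
    """1/f^exponent-filtered Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC
    x = np.fft.irfft(spec * gain, n=n)
    return x / x.std()


def _burst_waveform(shape: str, hz: float, t: np.ndarray,
                    phase: float, rng: np.random.Generator | None = None
                    ) -> np.ndarray:
    """Unit-amplitude ictal waveform sampled at times ``t``."""
    arg = 2 * np.pi * hz * t + phase
    if shape == "rhythmic":
        return np.sin(arg)
    if shape == "narrowband":
        # noise-textured rhythm: white noise bandpassed around hz; reads as
        # background texture rather than a stereotyped discharge
        from scipy import signal as sps
        n = t.size
        rate = 1.0 / (t[1] - t[0]) if n > 1 else 256.0
        noise = (rng or np.random.default_rng(0)).standard_normal(n + 512)
        sos = sps.butter(4, [hz - 1.5, hz + 1.5], btype="band", fs=rate,
                         output="sos")
        x = sps.sosfilt(sos, noise)[512:]
        return x / max(np.abs(x).max(), 1e-12)
    frac = (arg / (2 * np.pi)) % 1.0
    if shape == "spike_wave":
        # sharp spike occupying the first fifth of each cycle + slow wave
        spike = np.exp(-0.5 * ((frac - 0.1) / 0.035) ** 2)
        wave = 0.6 * np.sin(2 * np.pi * (frac - 0.2) / 0.8) * (frac >= 0.2)
        return spike + wave
    if shape == "polyspike":
        return np.sin(arg) * (0.6 + 0.4 * np.sin(3 * arg))
    raise ValueError(f"unknown burst shape {shape!r}")


def _place_seizures(rng: np.random.Generator, profile: PatientProfile
                    ) -> list[SeizureAnnotation]:
    """Place seizures uniformly at random subject to the separation gap."""
    n, dur = profile.n_seizures, profile.seizure_duration_s
    if n == 0:
        return []
    total = profile.recording_duration_s
    slot = dur + MIN_SEIZURE_GAP_S
    # rejection-free placement: draw gaps from the leftover slack
    slack = total - MIN_SEIZURE_GAP_S - n * slot
    cuts = np.sort(rng.uniform(0, slack, size=n))
    onsets = MIN_SEIZURE_GAP_S + cuts + slot * np.arange(n)
    return [SeizureAnnotation(round(float(o), 3), round(float(o) + dur, 3))
            for o in onsets]


def generate_recording(
    profile: PatientProfile,
    n_channels: int = 22,
    sample_rate_hz: float = 256.0,
) -> Recording:
    """Generate one annotated synthetic recording.

    Deterministic in ``profile.seed``: the same profile always produces a
    bit-identical signal and identical annotations.
    """
    rng = np.random.default_rng(profile.seed)
    rate = sample_rate_hz
    n = int(round(profile.recording_duration_s * rate))
    c = n_channels

    # shared low-rank sources + per-channel independent noise; the mixing
    # matrix is a cohort property (seeded separately) with small per-patient
    # jitter, mirroring the across-subject similarity of scalp topography
    k = min(5, c)
    sources = np.stack(
        [_pink_noise(rng, n, rate, profile.noise_exponent) for _ in range(k)]
    )
    mix_rng = np.random.default_rng(profile.mixing_seed)
    mixing = mix_rng.normal(0.0, 1.0, size=(c, k)) / np.sqrt(k)
    mixing = mixing + profile.spatial_jitter * rng.normal(size=(c, k)) / np.sqrt(k)
    background = 0.7 * mixing @ sources
    background += 0.7 * np.stack(
        [_pink_noise(rng, n, rate, profile.noise_exponent) for _ in range(c)]
    )
    if profile.am_sigma > 0:
        # stationary OU log-amplitude modulation shared across channels
        from scipy.signal import lfilter
        a = np.exp(-1.0 / (profile.am_tau_s * rate))
        x0 = rng.standard_normal()       # start in the stationary distribution
        eps = rng.standard_normal(n)
        ou, _ = lfilter([np.sqrt(1 - a * a)], [1.0, -a], eps, zi=[a * x0])
        background *= np.exp(profile.am_sigma * ou)[None, :]
    signal = profile.background_amp_uv * background

    annotations = _place_seizures(rng, profile)
    fam = FAMILIES[profile.seizure_family]
    t = np.arange(n) / rate
    burst_amp = profile.background_amp_uv * profile.seizure_amp_ratio
    for ann in annotations:
        i0, i1 = int(round(ann.onset_s * rate)), int(round(ann.offset_s * rate))
        seg_t = t[i0:i1] - ann.onset_s
        phase = rng.uniform(0, 2 * np.pi)
        wave = _burst_waveform(fam.shape, profile.spike_wave_hz, seg_t, phase,
                               rng=rng)
        # smooth onset/offset envelope with mild within-burst modulation
        m = i1 - i0
        ramp = min(int(0.5 * rate), m // 4)
        env = np.ones(m)
        if ramp > 0:
            env[:ramp] = np.linspace(0, 1, ramp)
            env[-ramp:] = np.linspace(1, 0, ramp)
        env *= 1.0 + 0.2 * np.sin(2 * np.pi * 0.7 * seg_t + rng.uniform(0, 2 * np.pi))
        spatial = 0.85 + 0.15 * rng.uniform(size=c)  # burst visible on all channels
        signal[:, i0:i1] += burst_amp * spatial[:, None] * (env * wave)[None, :]

    # interictal epileptiform discharges: family-morphology spikelets in
    # the background, clear of the seizures and their immediate surround
    if profile.interictal_spikes_per_min > 0:
        n_spikes = int(round(profile.interictal_spikes_per_min
                             * profile.recording_duration_s / 60.0))
        dur = profile.interictal_spike_duration_s
        m = int(round(dur * rate))
        amp = profile.background_amp_uv * profile.interictal_spike_amp_ratio
        env_sp = np.sin(np.linspace(0, np.pi, m)) ** 2
        placed = 0
        guard = 0
        while placed < n_spikes and guard < 50 * n_spikes:
            guard += 1
            start = rng.uniform(0, profile.recording_duration_s - dur)
            if any(a.onset_s - 2.0 < start < a.offset_s + 2.0
                   for a in annotations):
                continue
            i0 = int(round(start * rate))
            seg_t = t[i0:i0 + m] - start
            wave = _burst_waveform(fam.shape, profile.spike_wave_hz, seg_t,
                                   rng.uniform(0, 2 * np.pi), rng=rng)
            spatial = 0.85 + 0.15 * rng.uniform(size=c)
            signal[:, i0:i0 + m] += amp * spatial[:, None] * (env_sp * wave)[None, :]
            placed += 1

    return Recording(
        patient_id=profile.patient_id,
        channel_labels=[f"CH{i + 1:02d}" for i in range(c)],
        sample_rate_hz=rate,
        signal=signal,
        annotations=annotations,
        recording_id=f"{profile.patient_id}_r01",
    )


def cohort_profiles(spec: CohortSpec) -> list[PatientProfile]:
    """Expand a cohort spec into per-patient profiles with derived seeds."""
    root = np.random.SeedSequence(spec.seed)
    mixing_seed = int(root.generate_state(1)[0] % (2**31))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   root.spawn(spec.n_patients)]
    profiles = []
    id_cycle = 0
    for pid, seed in zip(spec.patient_ids(), child_seeds):
        if pid in spec.ood_patient_ids:
            family = spec.ood_family
        else:
            family = spec.id_families[id_cycle % len(spec.id_families)]
            id_cycle += 1
        profiles.append(PatientProfile(
            patient_id=pid,
            seizure_family=family,
            n_seizures=spec.n_seizures,
            seizure_duration_s=spec.seizure_duration_s,
            recording_duration_s=spec.recording_duration_s,
            seed=seed,
            mixing_seed=mixing_seed,
        ))
    return profiles


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate one recording per patient for a whole cohort."""
    return [
        generate_recording(p, n_channels=spec.n_channels,
                           sample_rate_hz=spec.sample_rate_hz)
        for p in cohort_profiles(spec)
    ]
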