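"""Synthetic cohort generator: determinism, morphology, cohort structure."""

import numpy as np
import pytest
from scipy.signal import periodogram

from szuq import CohortSpec, FAMILIES, PatientProfile, generate_cohort, \
    generate_recording


def _profile(**kw):
    kw.setdefault("patient_id", "p01")
    kw.setdefault("seed", 42)
    return PatientProfile(**kw)


class TestGenerateRecording:
    def test_shape_is_channels_by_duration_times_rate(self):
        rec = generate_recording(
            _profile(recording_duration_s=10.0, n_seizures=0),
            n_channels=22, sample_rate_hz=256.0)
        assert rec.signal.shape == (22, 2560)

    def test_identical_seed_identical_output(self):
        a = generate_recording(_profile())
        b = generate_recording(_profile())
        np.testing.assert_array_equal(a.signal, b.signal)
        assert a.annotations == b.annotations

    def test_annotations_match_injected_intervals(self):
        rec = generate_recording(_profile(n_seizures=3))
        assert len(rec.annotations) == 3
        for prev, nxt in zip(rec.annotations, rec.annotations[1:]):
            assert nxt.onset_s - prev.offset_s > 60.0

    def test_ictal_band_power_exceeds_background(self):
        """Periodogram oracle: power at the burst frequency, ictal windows
        vs background windows, ratio above 2."""
        prof = _profile(seizure_family="spike_wave_3hz")
        rec = generate_recording(prof)
        rate = rec.sample_rate_hz
        ann = rec.annotations[0]
        i0, i1 = int(ann.onset_s * rate), int(ann.offset_s * rate)
        n = i1 - i0
        bg0 = int((ann.offset_s + 35) * rate)
        ratios = []
        for ch in range(0, rec.n_channels, 7):
            f, p_ict = periodogram(rec.signal[ch, i0:i1], fs=rate)
            _, p_bg = periodogram(rec.signal[ch, bg0:bg0 + n], fs=rate)
            band = (f >= prof.spike_wave_hz - 1) & (f <= prof.spike_wave_hz + 1)
            ratios.append(p_ict[band].sum() / p_bg[band].sum())
        assert np.median(ratios) > 2.0

    def test_ictal_fraction_below_five_percent_for_defaults(self):
        rec = generate_recording(_profile())
        ictal = sum(a.duration_s for a in rec.annotations)
        assert ictal / rec.duration_s < 0.05

    def test_background_roughly_stationary_outside_seizures(self):
        """Per-third standard deviations of a seizure-free recording stay
        within a factor reflecting the slow amplitude modulation."""
        rec = generate_recording(_profile(recording_duration_s=300.0,
                                          n_seizures=0))
        thirds = np.array_split(rec.signal[0], 3)
        sds = [t.std() for t in thirds]
        assert max(sds) / min(sds) < 2.0

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            _profile(seizure_amp_ratio=0.5)
        with pytest.raises(ValueError):
            _profile(n_seizures=10, recording_duration_s=120.0)


class TestGenerateCohort:
    def test_cohort_structure_and_unique_ood_family(self):
        spec = CohortSpec(n_patients=6, ood_patient_ids=("p06",),
                          recording_duration_s=200.0, seed=5)
        recs = generate_cohort(spec)
        assert len(recs) == 6
        fams = {r.patient_id: r for r in recs}
        assert set(fams) == {f"p{i:02d}" for i in range(1, 7)}

    def test_ood_frequency_absent_from_in_distribution_set(self):
        spec = CohortSpec(n_patients=6, ood_patient_ids=("p06",),
                          recording_duration_s=200.0, seed=5)
        from szuq.simulate import cohort_profiles
        profiles = cohort_profiles(spec)
        id_hz = {p.spike_wave_hz for p in profiles if p.patient_id != "p06"}
        ood_hz = next(p.spike_wave_hz for p in profiles
                      if p.patient_id == "p06")
        assert ood_hz not in id_hz

    def test_deterministic_annotations(self):
        spec = CohortSpec(n_patients=3, ood_patient_ids=("p03",),
                          recording_duration_s=200.0, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.annotations == rb.annotations
            np.testing.assert_array_equal(ra.signal, rb.signal)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=1, ood_patient_ids=())

    def test_ood_family_must_differ(self):
        with pytest.raises(ValueError):
            CohortSpec(id_families=("rhythmic_9hz",))

    def test_unknown_ood_patient_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=3, ood_patient_ids=("p09",))


def test_family_registry_consistent():
    for fam in FAMILIES.values():
        assert fam.amp_ratio > 1
        assert fam.spike_wave_hz > 0
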