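"""Filtering, normalization, segmentation, and rebalancing contracts."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import firwin, freqz

from szuq import (Recording, SeizureAnnotation, SegmentDataset,
                  bandpass_and_dc_remove, normalize01, preprocess_recording,
                  rebalance, segment_recording)


def _rec(signal, anns=(), rate=256.0):
    labels = [f"c{i}" for i in range(signal.shape[0])]
    return Recording("p", labels, rate, signal, list(anns), "r01")


class TestBandpass:
    def test_pure_dc_removed(self):
        rec = _rec(np.full((1, 2560), 37.0))
        out = bandpass_and_dc_remove(rec)
        assert np.abs(out.signal).max() < 37.0 * 1e-6

    @pytest.mark.parametrize("freq,kind", [(30.0, "pass"), (100.0, "stop")])
    def test_response_matches_designed_filter(self, freq, kind):
        """Frequency-response oracle: the realized attenuation of a pure tone
        agrees with the design's |H|^2 (forward-backward application)."""
        t = np.arange(4096) / 256.0
        rec = _rec(np.sin(2 * np.pi * freq * t)[None, :] * 10.0)
        out = bandpass_and_dc_remove(rec)
        mid = slice(1024, 3072)  # avoid edge transients
        realized = out.signal[0, mid].std() / rec.signal[0, mid].std()
        taps = firwin(513, [1.0, 60.0], pass_zero=False, fs=256.0)
        w, h = freqz(taps, fs=256.0, worN=[freq])
        designed = np.abs(h[0]) ** 2  # filtfilt squares the response
        assert realized == pytest.approx(designed, abs=0.02)
        if kind == "pass":
            assert realized > 0.95
        else:
            assert realized < 0.10

    def test_high_cut_above_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 2560)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_and_dc_remove(rec, high_hz=128.0)

    def test_even_numtaps_rejected(self):
        rec = _rec(np.zeros((1, 2560)))
        with pytest.raises(ValueError, match="odd"):
            bandpass_and_dc_remove(rec, numtaps=512)


class TestNormalize01:
    def test_affine_map(self):
        out = normalize01(_rec(np.array([[-2.0, 0.0, 2.0]])))
        np.testing.assert_allclose(out.signal, [[0.0, 0.5, 1.0]])

    def test_already_unit_range_unchanged(self):
        sig = np.array([[0.0, 0.25, 1.0]])
        np.testing.assert_allclose(normalize01(_rec(sig)).signal, sig)

    def test_constant_channel_named_in_error(self):
        sig = np.vstack([np.arange(4.0), np.full(4, 7.0)])
        with pytest.raises(ValueError, match="c1"):
            normalize01(_rec(sig))

    def test_bounds_attained_per_channel(self):
        rng = np.random.default_rng(0)
        out = normalize01(_rec(rng.standard_normal((3, 100))))
        np.testing.assert_allclose(out.signal.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.signal.max(axis=1), 1.0, atol=1e-12)


class TestSegmentation:
    def test_hand_enumerated_example(self, short_recording):
        """10 s recording, seizure [3, 5): 3 ictal + 3 preictal + 5
        postictal windows, 11 total."""
        segs = segment_recording(short_recording)
        phases = Counter(s.phase for s in segs)
        assert phases == {"ictal": 3, "preictal": 3, "postictal": 5}
        assert [s.start_s for s in segs if s.phase == "ictal"] == [3.0, 3.5, 4.0]
        assert [s.start_s for s in segs if s.phase == "preictal"] == [0, 1, 2]
        assert [s.start_s for s in segs if s.phase == "postictal"] == \
            [5, 6, 7, 8, 9]

    @pytest.mark.parametrize("dur", [1, 2, 5, 9])
    def test_integer_seizure_yields_2d_minus_1_ictal_windows(self, dur):
        sig = np.random.default_rng(1).standard_normal((1, 256 * 200))
        rec = _rec(sig, [SeizureAnnotation(80.0, 80.0 + dur)])
        n_ictal = sum(1 for s in segment_recording(rec) if s.phase == "ictal")
        assert n_ictal == 2 * dur - 1

    def test_no_seizure_all_interictal(self):
        sig = np.random.default_rng(2).standard_normal((1, int(256 * 10.7)))
        segs = segment_recording(_rec(sig))
        assert len(segs) == 10
        assert {s.phase for s in segs} == {"interictal"}
        assert all(s.label == 0 for s in segs)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="window"):
            segment_recording(_rec(np.zeros((1, 128))))

    def test_label_phase_consistency_and_no_straddling(self, short_recording):
        rate = short_recording.sample_rate_hz
        for s in segment_recording(short_recording):
            assert (s.label == 1) == (s.phase == "ictal")
            assert s.data.shape == (2, 256)
            if s.label == 0:  # window must not intersect the ictal interval
                assert s.start_s + 1.0 <= 3.0 + 1e-9 or s.start_s >= 5.0 - 1e-9

    @given(onset=st.floats(31.0, 60.0), dur=st.floats(1.5, 8.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_windows_fully_inside_their_phase(self, onset, dur):
        sig = np.zeros((1, 256 * 100), dtype=np.float32)
        onset_r, offset_r = round(onset, 3), round(onset + dur, 3)
        rec = _rec(sig, [SeizureAnnotation(onset_r, offset_r)])
        segs = segment_recording(rec)
        ict = [s for s in segs if s.phase == "ictal"]
        assert ict, "a >=1.5 s seizure must yield at least one window"
        for s in ict:
            assert s.start_s >= onset_r - 1e-6
            assert s.start_s + 1.0 <= offset_r + 1e-6
        starts = [(s.start_s, s.label) for s in segs]
        assert len(set(starts)) == len(starts)


class TestRebalance:
    def _dataset(self, n_pos, n_neg):
        rng = np.random.default_rng(0)
        segs = []
        from szuq.preprocessing import Segment
        for i in range(n_pos):
            segs.append(Segment("p", "r", float(i), rng.random((2, 8)), 1,
                                "ictal"))
        for i in range(n_neg):
            segs.append(Segment("p", "r", 100.0 + i, rng.random((2, 8)), 0,
                                "interictal"))
        return SegmentDataset(segs)

    def test_five_to_one_subsampling(self):
        out = rebalance(self._dataset(10, 100), ratio=5, seed=1)
        labels = out.labels
        assert (labels == 1).sum() == 10 and (labels == 0).sum() == 50

    def test_capped_at_availability(self):
        out = rebalance(self._dataset(10, 30), ratio=5, seed=1)
        assert (out.labels == 0).sum() == 30

    def test_seeded_and_content_preserving(self):
        ds = self._dataset(5, 60)
        a = rebalance(ds, 5, seed=3)
        b = rebalance(ds, 5, seed=3)
        assert [s.start_s for s in a] == [s.start_s for s in b]
        assert all(s in ds.segments for s in a.segments)

    def test_requires_a_seizure_segment(self):
        with pytest.raises(ValueError, match="seizure"):
            rebalance(self._dataset(0, 10))


def test_full_pipeline_keeps_data_in_unit_interval(short_recording):
    segs = preprocess_recording(short_recording, numtaps=65)
    assert segs
    for s in segs:
        assert s.data.min() >= 0.0 and s.data.max() <= 1.0
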