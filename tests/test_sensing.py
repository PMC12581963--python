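"""Sense amplifier, auto-adjusting sensitivity, and interval-based VF detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacesense.errors import ContractViolationError, ParameterError
from pacesense.looping import loop_episode
from pacesense.recording import EgmRecording
from pacesense.sensing import (
    DetectionParams,
    SensingParams,
    band_rectify,
    detect_vf,
    run_detector,
    sense_events,
)
from pacesense.synth import VfModelParams, generate_vf_episode


def reference_sense_events(x, fs, p):
    """Straightforward sample-by-sample threshold-trajectory reference."""
    blank_n = max(int(round(p.blank_ms * fs / 1000.0)), 1)
    tau_n = p.decay_tau_ms * fs / 1000.0
    floor = p.sensitivity_floor_mv
    events = []
    blank_until = -1
    restart, decay_start = floor, 0
    had_event = False
    prev_below = True
    for i in range(len(x)):
        if i < blank_until:
            continue
        if had_event:
            thr = floor + (restart - floor) * math.exp(-(i - decay_start) / tau_n)
        else:
            thr = floor
        if x[i] >= thr and prev_below:
            events.append(i / fs)
            peak = max(x[i : min(i + blank_n, len(x))])
            restart = min(max(p.peak_fraction * peak, floor), p.max_threshold_mv)
            blank_until = i + blank_n
            decay_start = blank_until
            had_event = True
            prev_below = True
        else:
            prev_below = x[i] < thr
    return events


class TestBandRectify:
    def test_zero_in_zero_out(self):
        rec = EgmRecording(np.zeros(1024), fs=256.0)
        np.testing.assert_allclose(band_rectify(rec).samples, 0.0)

    def test_output_non_negative(self, reference_episode):
        assert np.all(band_rectify(reference_episode).samples >= 0)

    def test_rectification_doubles_tone_frequency(self):
        t = np.arange(4 * 256) / 256.0
        rec = EgmRecording(np.sin(2 * np.pi * 40.0 * t), fs=256.0)
        y = band_rectify(rec).samples[256:]  # discard settling
        spec = np.abs(np.fft.rfft(y - y.mean()))
        freqs = np.fft.rfftfreq(y.size, 1 / 256.0)
        assert abs(freqs[np.argmax(spec)] - 80.0) < 2.0

    def test_dc_removed(self):
        rec = EgmRecording(np.full(2048, 3.0), fs=256.0)
        assert np.all(band_rectify(rec).samples[1024:] < 1e-3)


class TestSenseEvents:
    def test_silence_gives_no_events(self):
        rec = EgmRecording(np.zeros(1024), fs=256.0)
        assert sense_events(rec) == []

    def test_isolated_peak_gives_one_event(self):
        x = np.zeros(1024)
        x[300] = 1.0
        assert len(sense_events(EgmRecording(x, fs=256.0))) == 1

    def test_periodic_peaks_sensed_every_cycle(self):
        x = np.zeros(20 * 256)
        step = int(0.2 * 256)
        x[step::step] = 0.5
        events = sense_events(EgmRecording(x, fs=256.0))
        intervals = np.diff(events) * 1000.0
        assert len(events) >= 90
        assert np.all(np.abs(intervals - 200.0) <= 4.0)

    def test_negative_samples_rejected(self):
        with pytest.raises(ContractViolationError):
            sense_events(EgmRecording(np.array([0.0, -1.0, 0.0]), fs=256.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_sample_by_sample_reference(self, seed):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.normal(0.2, 0.3, size=1000)) * (rng.random(1000) < 0.1)
        rec = EgmRecording(x, fs=256.0)
        p = SensingParams()
        assert sense_events(rec, p) == reference_sense_events(x, 256.0, p)

    def test_lowering_floor_only_increases_sensitivity(self, reference_episode):
        """A lower sensitivity floor senses at least as many events, and never
        later.  (Event-for-event set inclusion cannot hold for an adaptive
        detector: an extra early event at the lower floor shifts blanking and
        threshold restarts for everything that follows.)"""
        sensed = band_rectify(loop_episode(reference_episode, 30.0))
        counts, firsts = [], []
        for floor in (0.5, 0.3, 0.15):
            ev = sense_events(sensed, SensingParams(sensitivity_floor_mv=floor))
            counts.append(len(ev))
            firsts.append(ev[0])
        assert counts[0] <= counts[1] <= counts[2]
        assert firsts[0] >= firsts[1] >= firsts[2]


class TestDetectVf:
    def test_uniform_short_intervals_detect_at_required_count(self):
        events = [0.18 * k for k in range(40)]
        d = DetectionParams(vf_interval_ms=320.0, nid_x=18, nid_y=24, charge_time_s=8.0)
        res = detect_vf(events, d, episode_duration_s=60.0)
        assert res.detected
        assert res.t_detect_s == pytest.approx(events[18])  # 18 qualifying intervals
        assert res.t_therapy_s == pytest.approx(events[18] + 8.0)

    def test_slow_rhythm_not_detected(self):
        events = [1.0 * k for k in range(30)]
        assert not detect_vf(events, episode_duration_s=60.0).detected

    def test_empty_event_list(self):
        res = detect_vf([], episode_duration_s=60.0)
        assert not res.detected and res.t_detect_s is None

    def test_unsorted_events_rejected(self):
        with pytest.raises(ContractViolationError):
            detect_vf([0.5, 0.2, 0.9])

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(0.05, 1.5), min_size=0, max_size=60),
        st.integers(2, 12),
        st.integers(0, 8),
    )
    def test_matches_brute_force_count(self, intervals, nid_y, extra):
        nid_x = max(nid_y - extra, 1)
        events = list(np.cumsum([0.1] + intervals))
        d = DetectionParams(vf_interval_ms=320.0, nid_x=nid_x, nid_y=nid_y, charge_time_s=5.0)
        res = detect_vf(events, d, episode_duration_s=1e9)
        expected = None
        for j in range(1, len(events)):
            window = [
                events[k + 1] - events[k] < 0.320
                for k in range(max(0, j - nid_y), j)
            ]
            if sum(window) >= nid_x:
                expected = events[j]
                break
        if expected is None:
            assert not res.detected
        else:
            assert res.detected and res.t_detect_s == pytest.approx(expected)


class TestRunDetector:
    def test_clean_vf_detected_quickly(self):
        ep = loop_episode(generate_vf_episode(VfModelParams(target_mean_amp_mv=0.86, seed=2)), 60.0)
        res = run_detector(ep)
        assert res.detected and res.t_detect_s < 5.0

    @pytest.mark.parametrize("scale", [1.0, 2.0, 5.0])
    def test_detection_preserved_under_amplitude_scaling(self, scale):
        ep = loop_episode(generate_vf_episode(VfModelParams(target_mean_amp_mv=0.3, seed=6)), 60.0)
        assert run_detector(ep.with_samples(scale * ep.samples)).detected

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            SensingParams(peak_fraction=1.5)
        with pytest.raises(ParameterError):
            DetectionParams(nid_x=10, nid_y=5)
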