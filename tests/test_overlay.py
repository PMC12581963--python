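"""Pacing pulses, the pre-amplifier model, superposition and amplitude ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacesense.errors import AmplitudeUndefinedError, ParameterError
from pacesense.looping import loop_episode
from pacesense.overlay import (
    OverlaySpec,
    PreampParams,
    compute_ratio,
    mean_vf_amplitude,
    overlay_pacing,
    preamp_filter,
    synthesize_pulse,
)
from pacesense.recording import EgmRecording
from pacesense.sensing import band_rectify
from pacesense.synth import VfModelParams, generate_vf_episode

FS_INT = 32768.0


class TestSynthesizePulse:
    def test_plateau_sample_count(self):
        pulse = synthesize_pulse(5.0, 0.24, FS_INT)
        assert np.sum(pulse == 5.0) == pytest.approx(0.24e-3 * FS_INT, abs=1)

    def test_recharge_cancels_area(self):
        pulse = synthesize_pulse(1.0, 1.0, FS_INT, recharge=True)
        assert abs(np.sum(pulse)) <= 0.01 * np.sum(np.abs(pulse[pulse > 0]))
        assert np.min(pulse) == pytest.approx(-0.1)

    def test_polarity_mirror(self):
        np.testing.assert_allclose(
            synthesize_pulse(-1.0, 0.4, FS_INT), -synthesize_pulse(1.0, 0.4, FS_INT)
        )

    def test_subsample_width_rejected(self):
        with pytest.raises(ParameterError):
            synthesize_pulse(1.0, 0.001, FS_INT)


class TestPreampFilter:
    def _pulse_padded(self, amp=5.0, width=0.24):
        pulse = synthesize_pulse(amp, width, FS_INT)
        return np.concatenate([np.zeros(100), pulse, np.zeros(int(FS_INT))])

    def test_zero_in_zero_out(self):
        out = preamp_filter(np.zeros(1000))
        np.testing.assert_allclose(out, 0.0)

    def test_peak_reduced_slew_reduced_rebound_present(self):
        x = self._pulse_padded()
        y = preamp_filter(x)
        assert np.max(np.abs(y)) < np.max(np.abs(x))
        assert np.max(np.abs(np.diff(y))) < np.max(np.abs(np.diff(x)))
        assert np.min(y) < 0  # opposite-polarity rebound after the main deflection

    def test_ac_coupling_removes_long_run_mean(self):
        y = preamp_filter(self._pulse_padded())
        assert abs(np.mean(y)) <= 0.01 * np.max(np.abs(y))

    def test_time_invariant_superposition(self):
        one = np.zeros(int(3 * FS_INT))
        pulse = synthesize_pulse(1.0, 0.4, FS_INT)
        one[1000 : 1000 + pulse.size] = pulse
        two = one.copy()
        k = int(FS_INT)
        two[1000 + k : 1000 + k + pulse.size] += pulse
        y_one, y_two = preamp_filter(one), preamp_filter(two)
        shifted = np.zeros_like(y_one)
        shifted[k:] = y_one[:-k]
        np.testing.assert_allclose(y_two, y_one + shifted, atol=1e-9)


class TestMeanVfAmplitude:
    def test_sinusoid_closed_form(self):
        t = np.arange(int(4 * 256)) / 256.0
        rec = EgmRecording(0.5 * np.sin(2 * np.pi * 4.0 * t), fs=256.0)
        assert mean_vf_amplitude(rec) == pytest.approx(0.5, rel=0.02)

    def test_homogeneity(self, reference_episode):
        a = mean_vf_amplitude(reference_episode)
        b = mean_vf_amplitude(reference_episode.with_samples(2.0 * reference_episode.samples))
        assert b == pytest.approx(2.0 * a, rel=1e-9)

    def test_generator_calibration(self):
        ep = generate_vf_episode(VfModelParams(target_mean_amp_mv=0.86, seed=21))
        assert mean_vf_amplitude(ep) == pytest.approx(0.86, rel=0.10)

    def test_all_zero_undefined(self):
        with pytest.raises(AmplitudeUndefinedError):
            mean_vf_amplitude(EgmRecording(np.zeros(1024), fs=256.0))

    def test_short_recording_rejected(self):
        with pytest.raises(ParameterError):
            mean_vf_amplitude(EgmRecording(np.ones(100), fs=256.0))


class TestComputeRatio:
    # printed closest-case rows: sensed spike (mV) -> ratio against 0.86 mV VF
    TABLE = [
        (6.04, 7.02), (3.75, 4.36), (2.26, 2.63), (5.46, 6.35), (2.13, 2.48),
        (1.39, 1.62), (3.67, 4.27), (1.71, 1.99), (1.09, 1.27), (2.90, 3.37),
        (1.26, 1.47), (0.82, 0.95),
    ]

    @pytest.mark.parametrize("sensed,expected", TABLE)
    def test_closest_case_rows(self, sensed, expected):
        assert compute_ratio(sensed, 0.86) == expected

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.01, 100.0))
    def test_identity_ratio(self, x):
        assert compute_ratio(x, x) == 1.0

    def test_nonpositive_vf_rejected(self):
        with pytest.raises(ParameterError):
            compute_ratio(1.0, 0.0)


class TestOverlayPacing:
    def test_marker_count_and_spacing(self, reference_episode):
        rec = loop_episode(reference_episode, 60.0)
        out = overlay_pacing(rec, OverlaySpec(rate_ppm=60.0, spike_amp_mv=1.0, phase_s=0.0))
        times = [t for t, tag in out.markers if tag == "pace"]
        assert len(times) == 60
        np.testing.assert_allclose(np.diff(times), 1.0)

    def test_zero_amplitude_is_identity(self, reference_episode):
        rec = loop_episode(reference_episode, 60.0)
        assert overlay_pacing(rec, OverlaySpec(rate_ppm=60.0, spike_amp_mv=0.0)) is rec
        assert overlay_pacing(rec, OverlaySpec(rate_ppm=60.0, ratio=0.0)) is rec

    def test_exactly_one_amplitude_spec(self):
        with pytest.raises(ParameterError):
            OverlaySpec(rate_ppm=60.0)
        with pytest.raises(ParameterError):
            OverlaySpec(rate_ppm=60.0, spike_amp_mv=1.0, ratio=2.0)

    def test_artefact_independent_of_vf_content(self):
        """The added artefact is the same whatever VF it rides on, outside the
        short transition neighbourhoods."""
        spec = OverlaySpec(rate_ppm=60.0, spike_amp_mv=2.0, pulse_width_ms=1.0, phase_s=0.4)
        recs = [
            loop_episode(generate_vf_episode(VfModelParams(duration_s=8.0, seed=s)), 60.0)
            for s in (3, 8)
        ]
        arts = [overlay_pacing(r, spec).samples - r.samples for r in recs]
        diff = np.abs(arts[0] - arts[1])
        # transition smoothing touches <= 4 device samples per pulse
        assert np.sum(diff > 1e-9) <= 4 * 60

    def test_realized_sensed_amplitude_matches_request(self, reference_episode):
        rec = loop_episode(reference_episode, 60.0)
        target = 3.0
        out = overlay_pacing(
            rec, OverlaySpec(rate_ppm=80.0, spike_amp_mv=target, pulse_width_ms=0.4, phase_s=0.2)
        )
        art = band_rectify(EgmRecording(out.samples - rec.samples, fs=rec.fs))
        peaks = [
            np.max(art.samples[max(int(t * rec.fs) - 4, 0) : int(t * rec.fs) + 13])
            for t, tag in out.markers
            if tag == "pace"
        ]
        assert np.mean(peaks) == pytest.approx(target, rel=0.10)

    def test_ratio_on_zero_recording_undefined(self):
        rec = EgmRecording(np.zeros(60 * 256), fs=256.0)
        with pytest.raises(AmplitudeUndefinedError):
            overlay_pacing(rec, OverlaySpec(rate_ppm=60.0, ratio=2.0))

    def test_preamp_corner_validation(self):
        with pytest.raises(ParameterError):
            PreampParams(hp_corner_hz=100.0, lp_corner_hz=50.0)
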