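"""Band-pass, velocity surrogate, MAD threshold, hysteresis, consolidation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from thermobreath.errors import NotReadyError
from thermobreath.phase_detection import (
    EXHALE,
    INHALE,
    NEUTRAL,
    FilterSpec,
    PhaseConfig,
    bandpass,
    consolidate_flicker,
    design_bandpass,
    detect_phases,
    hysteresis_step,
    mad_threshold,
    rolling_mad_threshold,
    run_hysteresis,
    segments,
    velocity_surrogate,
)
from thermobreath.synthetic import SyntheticBreathParams, simulate_breath_signal

F_CAM = 25.0
T = np.arange(0, 60, 1 / F_CAM)


def expected_gain(freq: float) -> float:
    """Frequency-response oracle: squared magnitude of the designed filter
    (forward-backward application squares the response)."""
    _, h = sps.sosfreqz(design_bandpass(F_CAM), worN=[freq], fs=F_CAM)
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    def test_constant_signal_is_rejected_to_zero(self):
        out = bandpass(np.full(600, 30.0), F_CAM)
        assert np.max(np.abs(out)) < 1e-6

    @pytest.mark.parametrize("freq,amp_bound", [(0.3, None), (2.0, 0.1)])
    def test_sinusoid_amplitude_matches_response_oracle(self, freq, amp_bound):
        out = bandpass(np.sin(2 * np.pi * freq * T), F_CAM)
        # quadrature projection over whole cycles isolates the tone from the
        # slow filter edge transients
        n_cyc = int(freq * 40)
        sl = slice(250, 250 + int(n_cyc / freq * F_CAM))
        measured = 2 * np.abs(
            np.mean(out[sl] * np.exp(-2j * np.pi * freq * T[sl]))
        )
        assert measured == pytest.approx(expected_gain(freq), rel=0.05)
        if amp_bound is None:
            assert abs(measured - 1.0) < 0.05  # passband center
        else:
            assert measured < amp_bound  # stopband

    def test_too_short_signal_reports_not_ready(self):
        with pytest.raises(NotReadyError):
            bandpass(np.zeros(10), F_CAM)

    def test_zero_phase_cross_correlation_peaks_at_lag_zero(self):
        x = np.sin(2 * np.pi * 0.3 * T)
        y = bandpass(x, F_CAM)
        xc = sps.correlate(y, x)
        lags = sps.correlation_lags(len(y), len(x))
        assert lags[np.argmax(xc)] == 0


class TestVelocitySurrogate:
    def test_constant_input_gives_zero(self):
        v = velocity_surrogate(np.full(50, 3.0), 3)
        assert np.allclose(v[5:], 0.0)

    def test_ramp_gives_slope_times_window(self):
        m, W = 0.07, 4
        v = velocity_surrogate(m * np.arange(100), W)
        assert np.isnan(v[: 2 * W - 1]).all()
        assert np.allclose(v[2 * W - 1 :], m * W)

    def test_warming_ramp_is_positive(self):
        v = velocity_surrogate(0.01 * np.arange(60), 3)
        assert np.all(v[5:] > 0)  # warming -> exhalation sign


class TestMadThreshold:
    def test_constant_window_floors_at_epsilon(self):
        assert mad_threshold(np.full(21, 1.7), epsilon=1e-4) == pytest.approx(1e-4)

    def test_hand_computed_symmetric_window(self):
        theta = mad_threshold(np.array([-2, -1, 0, 1, 2]), 0.6, 0.001)
        assert theta == pytest.approx(0.601)

    @given(
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, scale, seed):
        v = np.random.default_rng(seed).normal(size=21)
        eps = 1e-4
        base = mad_threshold(v, 0.6, eps) - eps
        scaled = mad_threshold(scale * v, 0.6, eps) - eps
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-12)

    def test_rolling_threshold_skips_unavailable_velocity(self):
        v = np.concatenate([[np.nan] * 5, np.random.default_rng(0).normal(size=40)])
        theta = rolling_mad_threshold(v, 21)
        assert np.isnan(theta[:5]).all()
        assert np.all(theta[5:] >= 1e-4)


class TestHysteresis:
    def test_exhale_crossing_with_sufficient_dwell(self):
        assert hysteresis_step(INHALE, 5, 0.5, 0.3, 4)[0] == EXHALE

    def test_crossing_blocked_by_dwell_keeps_previous(self):
        label, tau = hysteresis_step(EXHALE, 2, -0.5, 0.3, 4)
        assert label == EXHALE and tau == 3

    def test_neutral_band_when_enabled(self):
        assert hysteresis_step(EXHALE, 9, 0.1, 0.3, 4, neutral=True)[0] == NEUTRAL

    def test_subthreshold_without_neutral_keeps_previous(self):
        assert hysteresis_step(EXHALE, 9, 0.1, 0.3, 4)[0] == EXHALE

    def test_persistence_resets_on_change_and_increments_otherwise(self):
        label, tau = hysteresis_step(INHALE, 7, 0.5, 0.3, 4)
        assert label == EXHALE and tau == 0
        label, tau = hysteresis_step(EXHALE, 0, 0.5, 0.3, 4)
        assert label == EXHALE and tau == 1

    def test_completed_interior_segments_respect_min_dwell(self):
        rng = np.random.default_rng(3)
        v = rng.normal(scale=1.0, size=400)
        theta = np.full(400, 0.3)
        n_min = 5
        labels, _ = run_hysteresis(v, theta, n_min)
        _, states, lengths = segments(labels)
        if len(lengths) > 2:
            assert np.all(lengths[1:-1] >= n_min)


class TestConsolidation:
    def test_short_middle_segment_merged(self):
        labels = np.array([1] * 10 + [-1] * 2 + [1] * 5)
        out = consolidate_flicker(labels, 3)
        assert np.all(out == 1)

    def test_long_middle_segment_untouched(self):
        labels = np.array([1] * 10 + [-1] * 5 + [1] * 5)
        assert np.array_equal(consolidate_flicker(labels, 3), labels)

    def test_iterates_to_fixed_point(self):
        labels = np.array([1] * 6 + [0] * 1 + [1] * 1 + [0] * 1 + [1] * 6)
        assert np.all(consolidate_flicker(labels, 3) == 1)

    def test_no_violations_remain_after_consolidation(self, rng):
        labels = rng.choice([-1, 0, 1], size=500)
        out = consolidate_flicker(labels, 4)
        _, states, lengths = segments(out)
        for i in range(1, len(states) - 1):
            violating = (
                states[i - 1] == states[i + 1]
                and states[i] != states[i - 1]
                and lengths[i] < 4
            )
            assert not violating


class TestDetectPhases:
    def test_noiseless_sinusoid_gives_alternating_breath_segments(self, clean_signal):
        trace = detect_phases(clean_signal.samples, F_CAM)
        n_exhale = int((trace.segment_states == 1).sum())
        assert abs(n_exhale - 18) <= 1  # 18 breaths in 60 s at 0.3 Hz
        interior = trace.segment_states[1:-1]
        assert np.all(interior[1:] != interior[:-1])  # strict alternation

    def test_constant_signal_has_single_unbroken_segment(self):
        trace = detect_phases(np.full(500, 30.0), F_CAM)
        assert len(trace.segment_states) == 1
        assert trace.segment_states[0] == 0

    def test_single_spike_does_not_change_segment_count(self, clean_signal):
        trace_clean = detect_phases(clean_signal.samples, F_CAM)
        spiked = clean_signal.samples.copy()
        spiked[750] += 10 * clean_signal.params.amplitude
        trace_spiked = detect_phases(spiked, F_CAM)
        assert len(trace_spiked.segment_states) == len(trace_clean.segment_states)

    @pytest.mark.parametrize("scale", [0.1, 10.0])
    def test_amplitude_scaling_leaves_phase_trace_essentially_unchanged(self, scale):
        params = SyntheticBreathParams(f_rr=0.3, noise_sd=0.02, drift_amp=0.0, seed=11)
        truth = simulate_breath_signal(params)
        base = detect_phases(truth.samples, F_CAM)
        scaled_sig = params.t0 + scale * (truth.samples - params.t0)
        scaled = detect_phases(scaled_sig, F_CAM)
        # threshold is MAD-proportional; only the epsilon floor can move a
        # boundary sample or two at extreme downscaling
        assert np.mean(scaled.labels == base.labels) > 0.995
        assert (scaled.segment_states == 1).sum() == (base.segment_states == 1).sum()

    @pytest.mark.parametrize("slope,expected", [(0.01, EXHALE), (-0.01, INHALE)])
    def test_sustained_trend_settles_on_matching_phase_label(self, slope, expected):
        """Warming velocity locks exhale, cooling locks inhale (sign convention).
        Asserted downstream of the velocity surrogate: a band-passed linear
        ramp is drift and rejected, so the trend is fed to the state machine
        directly."""
        v = velocity_surrogate(slope * np.arange(120), 3)
        theta = rolling_mad_threshold(v)
        labels, _ = run_hysteresis(np.nan_to_num(v, nan=0.0),
                                   np.nan_to_num(theta, nan=np.inf), n_min=3)
        assert labels[-1] == expected
        assert np.all(labels[20:] == expected)

    def test_not_ready_below_minimum_span(self):
        with pytest.raises(NotReadyError):
            detect_phases(np.full(100, 30.0), F_CAM)
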