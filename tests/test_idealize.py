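"""Filtering, baseline correction and half-amplitude idealization."""

import numpy as np
import pytest

import lipopore as lp
from lipopore.idealize import estimate_noise_sd

from conftest import rasterize_truth


def _flat_trace(value, duration=2.0, fs=5000.0, voltage=150.0):
    n = int(duration * fs)
    return lp.CurrentTrace(
        np.full(n, float(value)), fs, [lp.Epoch(voltage, 0.0, duration)]
    )


class TestLowpass:
    def test_dc_gain_is_unity(self):
        trace = _flat_trace(3.7)
        out = lp.lowpass_filter(trace, 200.0)
        np.testing.assert_allclose(out.samples, 3.7, rtol=1e-12)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        trace = _flat_trace(0.0)
        trace.samples[:] = rng.normal(0, 1, len(trace.samples))
        out = lp.lowpass_filter(trace, 200.0)
        assert np.var(out.samples) < 0.2 * np.var(trace.samples)

    def test_step_rise_time(self):
        # 10-90% rise time of the Gaussian response: 0.340/cutoff
        # (verified against the analytic step response Phi(t/sigma_t))
        fs, cutoff = 5000.0, 200.0
        trace = _flat_trace(0.0, duration=2.0, fs=fs)
        trace.samples[len(trace.samples) // 2 :] = 1.0
        out = lp.lowpass_filter(trace, cutoff)
        t = trace.time
        t10 = np.interp(0.1, out.samples, t)
        t90 = np.interp(0.9, out.samples, t)
        assert (t90 - t10) * cutoff == pytest.approx(0.3397, rel=0.02)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lp.lowpass_filter(_flat_trace(0.0), 2500.0)


class TestBaseline:
    def test_offset_closed_level_moved_to_zero(self, default_scheme):
        trace = lp.simulate_single_channel_trace(default_scheme, 150.0, 10.0, seed=5)
        shifted = trace.copy_with(trace.samples + 2.0)
        corrected = lp.baseline_correct(lp.lowpass_filter(shifted, 200.0))
        closed = corrected.samples[np.abs(corrected.samples) < 1.0]
        assert abs(np.median(closed)) < 0.05

    def test_already_zeroed_unchanged(self, default_scheme):
        trace = lp.simulate_single_channel_trace(default_scheme, 150.0, 10.0, seed=6)
        filt = lp.lowpass_filter(trace, 200.0)
        once = lp.baseline_correct(filt)
        twice = lp.baseline_correct(once)
        assert np.max(np.abs(twice.samples - once.samples)) < 0.05

    def test_offset_recovered_within_standard_error(self, default_scheme):
        # location-estimate precision on the closed-state samples
        noise_sd = 0.5
        trace = lp.simulate_single_channel_trace(
            default_scheme, 150.0, 30.0, noise_sd_pa=noise_sd, seed=7
        )
        true_offset = 1.37
        shifted = lp.lowpass_filter(trace.copy_with(trace.samples + true_offset), 200.0)
        corrected = lp.baseline_correct(shifted)
        estimated_offset = np.median(shifted.samples - corrected.samples)
        n_closed = int(0.5 * len(trace.samples))
        assert abs(estimated_offset - true_offset) < 3 * noise_sd / np.sqrt(n_closed) + 0.01

    def test_short_epoch_rejected(self):
        trace = _flat_trace(0.0, duration=0.5)
        with pytest.raises(ValueError):
            lp.baseline_correct(trace)


class TestDetectEvents:
    def test_noiseless_square_pulses_recovered_exactly(self):
        fs, amp = 5000.0, 3.0
        n = int(2.0 * fs)
        samples = np.zeros(n)
        pulses = [(0.2, 0.1), (0.6, 0.1), (1.4, 0.1)]  # (start, dwell) s
        for s, d in pulses:
            samples[int(s * fs) : int((s + d) * fs)] = amp
        trace = lp.CurrentTrace(samples, fs, [lp.Epoch(150.0, 0.0, 2.0)])
        events = lp.detect_events(trace, amp, min_dwell_s=0.001)
        assert len(events) == 3
        for ev, (s, d) in zip(events, pulses):
            assert ev.start_s == pytest.approx(s, abs=1 / fs)
            assert ev.dwell_s == pytest.approx(d, abs=1 / fs)
            assert ev.amplitude_pa == pytest.approx(amp)
            assert ev.level == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_noiseless_traces(self, seed):
        scheme = lp.GatingScheme(amplitude_cv=0.0)
        trace = lp.simulate_single_channel_trace(
            scheme, 150.0, 60.0, noise_sd_pa=0.0, seed=seed
        )
        fs = trace.sampling_rate
        min_samples = 2
        detected = lp.detect_events(trace, 2.25, min_dwell_s=min_samples / fs)
        expected = rasterize_truth(trace, min_samples)
        assert len(detected) == len(expected)
        for ev, (i0, i1, amp) in zip(detected, expected):
            assert round(ev.start_s * fs) == i0
            assert round((ev.start_s + ev.dwell_s) * fs) == i1
            assert ev.amplitude_pa == pytest.approx(amp, abs=1e-9)

    def test_subresolution_blip_discarded(self):
        fs = 5000.0
        samples = np.zeros(int(2 * fs))
        samples[5000:5002] = 3.0  # 0.4 ms blip, min_dwell 4 ms
        trace = lp.CurrentTrace(samples, fs, [lp.Epoch(150.0, 0.0, 2.0)])
        events = lp.detect_events(trace, 3.0, min_dwell_s=0.004)
        assert len(events) == 0

    def test_open_probability_near_half_on_noisy_fixture(self, default_scheme, events_150):
        # MC SE of the time-average of a symmetric two-state chain over 60 s
        tau_r = 1.0 / (
            1.0 / default_scheme.mean_open_dwell_s + 1.0 / default_scheme.mean_closed_dwell_s
        )
        se = np.sqrt(2 * 0.25 * tau_r / 60.0)
        assert abs(events_150.open_probability - 0.5) < 3 * se

    def test_dwell_p99_below_250ms(self, events_150):
        stats = lp.dwell_time_stats(events_150)
        assert stats["p99_dwell_s"] <= 0.250

    def test_sign_flip_invariance(self, default_scheme):
        trace = lp.simulate_single_channel_trace(default_scheme, 150.0, 20.0, seed=13)
        prepared = lp.baseline_correct(lp.lowpass_filter(trace, 200.0))
        flipped = lp.CurrentTrace(
            -prepared.samples, prepared.sampling_rate,
            [lp.Epoch(-150.0, 0.0, 20.0)], dict(prepared.metadata),
        )
        ev_pos = lp.detect_events(prepared, 2.775)
        ev_neg = lp.detect_events(flipped, -2.775)
        assert len(ev_pos) == len(ev_neg)
        np.testing.assert_allclose(ev_pos.dwells, ev_neg.dwells)
        np.testing.assert_allclose(ev_pos.amplitudes, -ev_neg.amplitudes)

    def test_unresolvable_open_level_rejected(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(0, 1.0, 10000)
        trace = lp.CurrentTrace(samples, 5000.0, [lp.Epoch(150.0, 0.0, 2.0)])
        with pytest.raises(ValueError, match="unresolvable"):
            lp.detect_events(trace, 0.5, min_dwell_s=0.002)
        with pytest.raises(ValueError):
            lp.detect_events(trace, 0.0)

    def test_total_open_time_bounded(self, events_150):
        assert 0.0 <= events_150.open_probability <= 1.0
        assert events_150.total_open_time_s <= events_150.epoch_duration_s


class TestDwellStats:
    def test_single_event(self):
        events = lp.EventList.from_events([(0.1, 0.05, 3.0, 1)], 150.0, 1.0)
        with pytest.warns(UserWarning):
            stats = lp.dwell_time_stats(events)
        assert stats["n_events"] == 1
        assert stats["mean_dwell_s"] == stats["median_dwell_s"] == 0.05

    def test_exponential_sample_mean_clt(self):
        rng = np.random.default_rng(17)
        dwells = rng.exponential(0.060, 500)
        events = lp.EventList.from_events(
            [(i * 1.0, d, 3.0, 1) for i, d in enumerate(dwells)], 150.0, 600.0
        )
        stats = lp.dwell_time_stats(events)
        assert abs(stats["mean_dwell_s"] - 0.060) < 3 * 0.060 / np.sqrt(500)

    def test_empty_rejected(self):
        events = lp.EventList([], 150.0, 1.0)
        with pytest.raises(ValueError):
            lp.dwell_time_stats(events)


def test_noise_sd_estimator_on_known_noise():
    rng = np.random.default_rng(1)
    assert estimate_noise_sd(rng.normal(0, 0.5, 50000)) == pytest.approx(0.5, rel=0.05)
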