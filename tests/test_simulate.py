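"""Generator contracts: reproducibility, stationarity, exact laws."""

import numpy as np
import pytest

import lipopore as lp


def test_identical_seeds_give_identical_outputs():
    scheme = lp.GatingScheme()
    a = lp.simulate_single_channel_trace(scheme, 150.0, 5.0, seed=3)
    b = lp.simulate_single_channel_trace(scheme, 150.0, 5.0, seed=3)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert len(a.true_events) == len(b.true_events)

    da = lp.simulate_dose_response([1, 2, 4], noise_cv=0.2, seed=5)
    db = lp.simulate_dose_response([1, 2, 4], noise_cv=0.2, seed=5)
    assert da.equals(db)

    ta = lp.simulate_thermogram([lp.ThermoPeakSpec(41.3, 0.5, 1.0)], noise_sd=0.1, seed=9)
    tb = lp.simulate_thermogram([lp.ThermoPeakSpec(41.3, 0.5, 1.0)], noise_sd=0.1, seed=9)
    np.testing.assert_array_equal(ta.excess_cp, tb.excess_cp)


def test_two_state_occupancy_converges_to_half():
    # symmetric dwells: stationary open fraction 1/2; Monte-Carlo SE of the
    # time average is sqrt(2 p (1-p) tau_r / T) with tau_r the relaxation time
    scheme = lp.GatingScheme(amplitude_cv=0.0)
    trace = lp.simulate_single_channel_trace(scheme, 150.0, 120.0, noise_sd_pa=0.0, seed=21)
    frac = np.mean(trace.samples != 0.0)
    tau_r = 1.0 / (1.0 / scheme.mean_open_dwell_s + 1.0 / scheme.mean_closed_dwell_s)
    se = np.sqrt(2 * 0.25 * tau_r / 120.0)
    assert abs(frac - 0.5) < 3 * se


def test_substate_fraction_matches_weight():
    scheme = lp.GatingScheme(large_weight_fn=lambda v: 0.7, amplitude_cv=0.0)
    trace = lp.simulate_single_channel_trace(scheme, 150.0, 60.0, noise_sd_pa=0.0, seed=4)
    amps = trace.true_events.amplitudes
    large = np.isclose(amps, 22.0 * 150.0 * 1e-3)
    n = len(amps)
    se = np.sqrt(0.7 * 0.3 / n)
    assert abs(large.mean() - 0.7) < 3 * se


def test_default_scheme_dwells_below_250ms(default_scheme):
    trace = lp.simulate_single_channel_trace(default_scheme, 150.0, 60.0, seed=8)
    assert np.percentile(trace.true_events.dwells, 99) <= 0.250


def test_zero_voltage_trace_is_pure_noise():
    scheme = lp.GatingScheme(amplitude_cv=0.0)
    trace = lp.simulate_single_channel_trace(scheme, 0.0, 5.0, noise_sd_pa=0.0, seed=1)
    assert np.all(trace.samples == 0.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"duration_s": -1.0},
        {"duration_s": 0.5},  # < 10 gating cycles
        {"sampling_rate": 100.0},
        {"sampling_rate": -5.0},
    ],
)
def test_single_channel_bad_parameters_rejected(default_scheme, kwargs):
    args = {"voltage_mv": 150.0, "duration_s": 30.0, "sampling_rate": 5000.0}
    args.update(kwargs)
    with pytest.raises(ValueError):
        lp.simulate_single_channel_trace(default_scheme, **args)


def test_scheme_invariants_enforced():
    with pytest.raises(ValueError):
        lp.GatingScheme(conductance_small_ps=22.0, conductance_large_ps=15.0)
    with pytest.raises(ValueError):
        lp.GatingScheme(mean_open_dwell_s=-0.1)


class TestMacroscopic:
    def test_constant_per_epoch_without_components(self):
        params = lp.MacroKineticsParams(amp_fast_pa=0.0, amp_slow_pa=0.0)
        trace = lp.simulate_macroscopic_trace(params, [(150.0, 5.0)], noise_sd_pa=0.0)
        np.testing.assert_allclose(trace.samples, params.steady_positive_pa)

    def test_unit_jump_ratio_is_continuous(self):
        params = lp.MacroKineticsParams(
            amp_fast_pa=0.0, amp_slow_pa=0.0, jump_ratio=1.0,
            steady_positive_pa=500.0, steady_negative_pa=-500.0,
        )
        trace = lp.simulate_macroscopic_trace(
            params, [(150.0, 5.0), (-150.0, 5.0)], noise_sd_pa=0.0
        )
        i_switch = int(5.0 * trace.sampling_rate)
        assert abs(abs(trace.samples[i_switch]) - abs(trace.samples[i_switch - 1])) < 1.0

    def test_jump_divides_absolute_current(self):
        params = lp.MacroKineticsParams(amp_fast_pa=0.0, amp_slow_pa=0.0)
        trace = lp.simulate_macroscopic_trace(
            params, [(150.0, 5.0), (-150.0, 5.0)], noise_sd_pa=0.0
        )
        i_switch = int(5.0 * trace.sampling_rate)
        expected = params.steady_positive_pa / params.jump_ratio
        assert abs(trace.samples[i_switch]) == pytest.approx(expected, rel=0.02)

    def test_empty_or_degenerate_protocol_rejected(self):
        with pytest.raises(ValueError):
            lp.simulate_macroscopic_trace(lp.MacroKineticsParams(), [])
        with pytest.raises(ValueError):
            lp.simulate_macroscopic_trace(lp.MacroKineticsParams(), [(150.0, 0.0)])


class TestDose:
    def test_square_law_exact_ratios(self):
        table = lp.simulate_dose_response([1.0, 2.0, 4.0], 2.0, 1.0, 0.0)
        np.testing.assert_allclose(table["current_pA"], [1.0, 4.0, 16.0])

    def test_linear_law_doubles(self):
        table = lp.simulate_dose_response([3.0, 6.0], 1.0, 2.5, 0.0)
        assert table["current_pA"].iloc[1] == pytest.approx(2 * table["current_pA"].iloc[0])

    def test_log_linearity_exact(self):
        c = np.array([0.5, 1, 2, 5, 10])
        table = lp.simulate_dose_response(c, 2.0, 7.0, 0.0)
        slopes = np.diff(np.log(table["current_pA"])) / np.diff(np.log(c))
        np.testing.assert_allclose(slopes, 2.0, atol=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            lp.simulate_dose_response([1.0, -2.0])


class TestChannelCounts:
    def test_flat_when_q_and_alpha_zero(self):
        table = lp.simulate_channel_counts(250.0, 0.0, 0.0, [-100, 0, 100])
        np.testing.assert_allclose(table["n_ch"], 250.0)

    def test_value_at_150mv_matches_direct_evaluation(self):
        # N0 exp(q u + a u^2) at +150 mV, 298.15 K = 317.49 (independent eval)
        table = lp.simulate_channel_counts(300.0, -0.037, 0.008, [150.0])
        assert table["n_ch"].iloc[0] == pytest.approx(317.491, abs=0.01)

    def test_bad_temperature_rejected(self):
        with pytest.raises(ValueError):
            lp.simulate_channel_counts(temperature_k=-1.0)


class TestThermogramGenerator:
    def test_single_peak_maximum_on_grid(self):
        scan = lp.simulate_thermogram([lp.ThermoPeakSpec(41.3, 0.5, 1.0)], (35, 45), 0.02)
        assert scan.temperature_c[np.argmax(scan.excess_cp)] == pytest.approx(41.3, abs=0.011)

    def test_zero_peaks_flat_baseline(self):
        scan = lp.simulate_thermogram([], (30, 40), 0.1)
        assert np.ptp(scan.excess_cp) == 0.0

    def test_two_peaks_separated(self):
        scan = lp.dppc_thermogram()
        from scipy.signal import find_peaks

        idx, _ = find_peaks(scan.excess_cp, height=0.05)
        temps = scan.temperature_c[idx]
        assert any(abs(t - 34.1) < 0.1 for t in temps)
        assert any(abs(t - 41.3) < 0.1 for t in temps)

    def test_peak_outside_range_rejected(self):
        with pytest.raises(ValueError):
            lp.simulate_thermogram([lp.ThermoPeakSpec(60.0, 0.5, 1.0)], (30, 50), 0.02)
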