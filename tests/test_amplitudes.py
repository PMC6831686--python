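"""Amplitude histograms, mixture decomposition and g-V curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipopore as lp
from lipopore.amplitudes import AmplitudeHistogram, MixtureComponent, MixtureFit


class TestHistogram:
    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=50, max_size=400),
        st.floats(0.01, 1.0),
    )
    def test_count_conservation_any_binning(self, amps, width):
        hist = lp.build_histogram(np.array(amps), bin_width_pa=width)
        assert hist.n_total == len(amps)

    def test_identical_amplitudes_single_bin(self):
        hist = lp.build_histogram(np.full(300, 2.5), bin_width_pa=0.1)
        assert np.count_nonzero(hist.counts) == 1
        assert hist.counts.max() == 300

    def test_bimodal_fixture_two_maxima(self):
        rng = np.random.default_rng(0)
        amps = np.concatenate([rng.normal(2.25, 0.12, 300), rng.normal(3.3, 0.12, 300)])
        hist = lp.build_histogram(amps, bin_width_pa=0.15)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(hist.counts, height=0.3 * hist.counts.max())
        assert len(idx) == 2

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            lp.build_histogram(np.ones(10))

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            lp.build_histogram(np.random.default_rng(0).normal(size=100), bin_width_pa=-0.1)


class TestMixture:
    def test_unimodal_selects_one_component(self):
        rng = np.random.default_rng(42)
        amps = rng.normal(2.25, 0.15, 500)
        fit = lp.fit_mixture(lp.build_histogram(amps), 3)
        assert fit.n_components == 1
        assert fit.selected
        comp = fit.components[0]
        assert comp.mean_pa == pytest.approx(2.25, abs=3 * 0.15 / np.sqrt(500))

    def test_bimodal_selects_two_and_recovers_areas(self):
        rng = np.random.default_rng(42)
        amps = np.concatenate([rng.normal(3.3, 0.15, 350), rng.normal(2.25, 0.15, 150)])
        fit = lp.fit_mixture(lp.build_histogram(amps), 3)
        assert fit.n_components == 2
        assert fit.selected
        small, large = fit.components
        assert small.area == pytest.approx(150, abs=3 * max(small.area_se, np.sqrt(150)))
        assert large.area == pytest.approx(350, abs=3 * max(large.area_se, np.sqrt(350)))
        assert fit.total_area == pytest.approx(fit.n_total, rel=0.01)

    def test_uniform_shape_flagged_as_misspecified(self):
        hist = AmplitudeHistogram(np.linspace(0, 1, 51), np.full(50, 5000))
        fit = lp.fit_mixture(hist, 2)
        assert not fit.selected

    def test_insufficient_occupied_bins_rejected(self):
        hist = AmplitudeHistogram([0, 1, 2, 3], [100, 0, 0])
        with pytest.raises(ValueError):
            lp.fit_mixture(hist, 2)

    def test_mean_precision_improves_with_n(self):
        rng = np.random.default_rng(3)
        ses = []
        for n in (200, 2000):
            amps = rng.normal(2.25, 0.15, n)
            fit = lp.fit_mixture(lp.build_histogram(amps), 1)
            ses.append(fit.components[0].mean_se)
        assert ses[1] < 0.55 * ses[0]  # ~ 1/sqrt(10)


def _fit_from_areas(a_small, a_large):
    comps = [
        MixtureComponent(2.25, 0.1, a_small),
        MixtureComponent(3.3, 0.1, a_large),
    ]
    return MixtureFit(comps, 0.0, 1.0, 1, int(a_small + a_large), 150.0)


class TestSubstateRatio:
    def test_equal_areas_give_unity(self):
        assert lp.substate_ratio(_fit_from_areas(200, 200)) == pytest.approx(1.0)

    def test_mirror_relabelling_inverts_ratio(self):
        fit = _fit_from_areas(150, 350)
        mirrored = _fit_from_areas(350, 150)
        assert lp.substate_ratio(fit) * lp.substate_ratio(mirrored) == pytest.approx(1.0)

    def test_single_component_rejected(self):
        fit = MixtureFit([MixtureComponent(2.25, 0.1, 300)], 0, 1, 1, 300)
        with pytest.raises(ValueError):
            lp.substate_ratio(fit)

    def test_weight_07_fixture_recovers_ratio(self, events_weight07):
        fit = lp.fit_mixture(lp.build_histogram(events_weight07), 2)
        assert fit.n_components == 2
        ratio = lp.substate_ratio(fit)
        # binomial sampling error of the 0.7/0.3 split, delta method on the odds
        n = len(events_weight07)
        se = np.sqrt(0.7 * 0.3 / n) / 0.3**2
        assert ratio == pytest.approx(0.7 / 0.3, abs=3 * se + 0.1)

    def test_voltage_sign_selects_substate(self, events_150, events_m150):
        # large substate favored at +150 mV, small at -150 mV
        fit_pos = lp.fit_mixture(lp.build_histogram(events_150), 2)
        fit_neg = lp.fit_mixture(lp.build_histogram(events_m150), 2)
        assert lp.substate_ratio(fit_pos) > 1.0
        assert lp.substate_ratio(fit_neg) < 1.0


class TestGVCurve:
    def test_ohmic_amplitudes_give_flat_curve(self):
        g = 17.0
        fits = [
            MixtureFit([MixtureComponent(g * v * 1e-3, 0.1, 300)], 0, 1, 1, 300, v)
            for v in (-150.0, -100.0, 100.0, 150.0)
        ]
        curve = lp.gv_curve([(f.voltage_mv, f) for f in fits])
        np.testing.assert_allclose(curve.points["conductance_pS"], g, rtol=1e-9)

    def test_default_fixture_conductance_ratio_near_1p5(self, events_150, events_m150):
        fit_pos = lp.fit_mixture(lp.build_histogram(events_150), 2)
        fit_neg = lp.fit_mixture(lp.build_histogram(events_m150), 2)
        curve = lp.gv_curve([(150.0, fit_pos), (-150.0, fit_neg)])
        ratio = curve.asymmetry_ratio(150.0, -150.0)
        assert ratio == pytest.approx(22.0 / 15.0, rel=0.12)

    def test_ramp_fixture_recovers_asymmetry(self):
        # conductance ramps 1.4-fold from +50 to +200 mV
        voltages = np.array([50.0, 100.0, 150.0, 200.0])
        g = 15.0 * (1 + 0.4 * (voltages - 50.0) / 150.0)
        fits = [
            (v, MixtureFit([MixtureComponent(gi * v * 1e-3, 0.1, 300)], 0, 1, 1, 300, v))
            for v, gi in zip(voltages, g)
        ]
        curve = lp.gv_curve(fits)
        assert curve.asymmetry_ratio(200.0, 50.0) == pytest.approx(1.4, rel=1e-9)

    def test_zero_voltage_rejected(self):
        fit = _fit_from_areas(100, 100)
        with pytest.raises(ValueError):
            lp.gv_curve([(0.0, fit), (100.0, fit)])

    def test_needs_two_voltages(self):
        with pytest.raises(ValueError):
            lp.gv_curve([(100.0, _fit_from_areas(100, 100))])
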