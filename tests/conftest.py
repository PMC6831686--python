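import numpy as np
import pytest

import lipopore as lp


def rasterize_truth(trace, min_samples):
    """Independent sampling-grid oracle for the embedded event log.

    Paints the true openings onto the sample grid, run-length encodes the
    result and drops runs shorter than ``min_samples`` — what an ideal
    detector sees at this sampling rate.  Returns (i0, i1, amplitude) runs.
    """
    fs = trace.sampling_rate
    n = len(trace.samples)
    amp = np.zeros(n)
    for ev in trace.true_events:
        i0 = int(round(ev.start_s * fs))
        i1 = int(round((ev.start_s + ev.dwell_s) * fs))
        amp[i0:i1] = ev.amplitude_pa
    mask = (amp != 0).view(np.int8)
    d = np.diff(np.concatenate(([0], mask, [0])))
    runs = []
    for i0, i1 in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if i1 - i0 >= min_samples:
            runs.append((int(i0), int(i1), float(np.mean(amp[i0:i1]))))
    return runs


@pytest.fixture(scope="session")
def default_scheme():
    return lp.GatingScheme()


@pytest.fixture(scope="session")
def prepared_150(default_scheme):
    """Noisy 60 s recording at +150 mV, filtered and baseline-corrected."""
    trace = lp.simulate_single_channel_trace(default_scheme, 150.0, 60.0, seed=11)
    return lp.baseline_correct(lp.lowpass_filter(trace, 200.0))


@pytest.fixture(scope="session")
def events_150(default_scheme, prepared_150):
    level = (
        (default_scheme.conductance_small_ps + default_scheme.conductance_large_ps)
        / 2.0 * 150.0 * 1e-3
    )
    return lp.detect_events(prepared_150, level)


@pytest.fixture(scope="session")
def events_m150(default_scheme):
    trace = lp.simulate_single_channel_trace(default_scheme, -150.0, 60.0, seed=12)
    prepared = lp.baseline_correct(lp.lowpass_filter(trace, 200.0))
    level = (
        (default_scheme.conductance_small_ps + default_scheme.conductance_large_ps)
        / 2.0 * -150.0 * 1e-3
    )
    return lp.detect_events(prepared, level)


@pytest.fixture(scope="session")
def events_weight07():
    """120 s fixture whose openings are the large substate with p = 0.7."""
    scheme = lp.GatingScheme(large_weight_fn=lambda v: 0.7)
    trace = lp.simulate_single_channel_trace(scheme, 150.0, 120.0, seed=2)
    prepared = lp.baseline_correct(lp.lowpass_filter(trace, 200.0))
    return lp.detect_events(prepared, 18.5 * 150.0 * 1e-3)
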