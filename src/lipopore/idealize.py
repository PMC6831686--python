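"""Trace conditioning and half-amplitude event idealization.

The preprocessing chain mirrors standard single-channel practice: a
zero-phase Gaussian low-pass filter (the digital stage of the recording
chain), per-epoch baseline correction that pins the closed level to 0 pA,
then half-amplitude threshold idealization into discrete openings.  Open
probability is reported as the fraction of epoch time with any conducting
level — the only definition available without per-channel bookkeeping.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .trace import ChannelEvent, CurrentTrace, EventList

#: Gaussian-filter rise time Tr = sqrt(2*pi)*sigma_t = 0.3321/f_c (the
#: reciprocal-max-slope definition used throughout single-channel work).
GAUSSIAN_RISE_TIME_CONST = 0.3321

# sigma_t of a Gaussian filter with -3 dB (amplitude 1/sqrt(2)) at f_c
_SIGMA_T_CONST = math.sqrt(math.log(2.0)) / (2.0 * math.pi)


def filter_rise_time_s(cutoff_hz: float) -> float:
    """Nominal rise time of the Gaussian low-pass at the given cutoff."""
    return GAUSSIAN_RISE_TIME_CONST / cutoff_hz


def lowpass_filter(trace: CurrentTrace, cutoff_hz: float = 200.0) -> CurrentTrace:
    """Zero-phase Gaussian low-pass with the -3 dB point at ``cutoff_hz``.

    DC gain is exactly 1 (a constant trace passes through unchanged).  The
    applied cutoff is recorded in the trace metadata.
    """
    nyquist = trace.sampling_rate / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={nyquist} Hz), got {cutoff_hz}"
        )
    sigma_samples = _SIGMA_T_CONST / cutoff_hz * trace.sampling_rate
    filtered = gaussian_filter1d(trace.samples, sigma_samples, mode="nearest")
    return trace.copy_with(filtered, filter_cutoff_hz=cutoff_hz)


def estimate_noise_sd(samples: np.ndarray) -> float:
    """Robust noise sd from first differences (MAD-based, outlier-immune)."""
    d = np.diff(samples)
    return float(np.median(np.abs(d - np.median(d))) / 0.67448975 / math.sqrt(2.0))


def _histogram_mode(samples: np.ndarray) -> tuple[float, bool]:
    """Mode of the all-points histogram with parabolic refinement.

    Returns (mode, dominant): ``dominant`` is False when no bin clearly
    dominates, in which case the caller should fall back to the median.
    """
    n = len(samples)
    # Freedman-Diaconis width, guarded for near-constant input
    q75, q25 = np.percentile(samples, [75, 25])
    width = 2.0 * (q75 - q25) / max(n, 1) ** (1.0 / 3.0)
    if width <= 0:
        return float(np.median(samples)), True
    counts, edges = np.histogram(samples, bins=np.arange(samples.min(), samples.max() + width, width))
    if len(counts) < 3:
        return float(np.median(samples)), True
    k = int(np.argmax(counts))
    dominant = counts[k] > 1.5 * np.median(counts[counts > 0])
    centers = (edges[:-1] + edges[1:]) / 2.0
    if 0 < k < len(counts) - 1:
        y0, y1, y2 = counts[k - 1], counts[k], counts[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            k_frac = 0.5 * (y0 - y2) / denom
            return float(centers[k] + k_frac * width), dominant
    return float(centers[k]), dominant


def baseline_correct(trace: CurrentTrace) -> CurrentTrace:
    """Subtract the per-epoch closed-level baseline.

    The baseline is the mode of the all-points histogram of each epoch (the
    closed level dominates at open probabilities near or below 0.5).  If no
    dominant mode is found a warning is emitted and the median is used.
    """
    protocol = trace.protocol or [None]
    corrected = trace.samples.copy()
    for ep in protocol:
        sl = slice(None) if ep is None else trace.epoch_slice(ep)
        seg = corrected[sl]
        if len(seg) < trace.sampling_rate:  # need >= 1 s per epoch
            raise ValueError("each epoch needs at least 1 s of data for baseline estimation")
        mode, dominant = _histogram_mode(seg)
        if not dominant:
            warnings.warn(
                "no dominant closed-level mode; falling back to the median",
                stacklevel=2,
            )
            mode = float(np.median(seg))
        corrected[sl] = seg - mode
    return trace.copy_with(corrected, baseline_corrected=True)


def _stabilize_levels(seg_levels: np.ndarray, min_samples: int) -> np.ndarray:
    """Relabel level runs shorter than ``min_samples`` to a neighbouring level.

    Short runs take the level of the preceding sustained run (or the first
    sustained run when they open the segment).  If no run is sustained the
    whole segment takes its majority level.
    """
    change = np.flatnonzero(np.diff(seg_levels)) + 1
    bounds = np.concatenate(([0], change, [len(seg_levels)]))
    runs = [(b0, b1, int(seg_levels[b0])) for b0, b1 in zip(bounds[:-1], bounds[1:])]
    if len(runs) == 1:
        return seg_levels
    long_runs = [i for i, (b0, b1, _) in enumerate(runs) if b1 - b0 >= min_samples]
    out = seg_levels.copy()
    if not long_runs:
        vals, counts = np.unique(seg_levels, return_counts=True)
        out[:] = vals[np.argmax(counts)]
        return out
    for i, (b0, b1, _) in enumerate(runs):
        if b1 - b0 < min_samples:
            prev = [j for j in long_runs if j < i]
            donor = prev[-1] if prev else long_runs[0]
            out[b0:b1] = runs[donor][2]
    return out


def detect_events(
    trace: CurrentTrace,
    open_level_pa: float,
    min_dwell_s: float | None = None,
    epoch_index: int = 0,
) -> EventList:
    """Half-amplitude threshold idealization of one constant-voltage epoch.

    Samples beyond 50% of ``open_level_pa`` (the single-channel open-level
    estimate, signed like the epoch current) mark open segments.  Retained
    open segments shorter than ``min_dwell_s`` (default 2x the filter rise
    time, 3.3 ms at a 200 Hz cutoff) are discarded; each surviving segment
    becomes one event whose amplitude is its mean current.  Segments where
    the current exceeds multiples of the open level (simultaneous channels)
    are split at level boundaries into separate level-1/level-2/... events.
    """
    if open_level_pa == 0:
        raise ValueError("open_level_pa must be nonzero")
    if not trace.protocol:
        raise ValueError("trace has no voltage protocol")
    epoch = trace.protocol[epoch_index]
    seg = trace.epoch_samples(epoch)
    fs = trace.sampling_rate

    noise_sd = estimate_noise_sd(seg)
    if abs(open_level_pa) < 3.0 * noise_sd:
        raise ValueError(
            f"open_level_pa ({open_level_pa} pA) is within 3x the noise sd "
            f"({noise_sd:.3g} pA); events are unresolvable"
        )
    if min_dwell_s is None:
        cutoff = trace.metadata.get("filter_cutoff_hz")
        min_dwell_s = 2.0 * filter_rise_time_s(cutoff) if cutoff else 2.0 / fs

    sign = 1.0 if open_level_pa > 0 else -1.0
    x = sign * seg
    unit = abs(open_level_pa)
    # level index per sample: 0 closed, k when beyond (k - 1/2) * unit
    levels = np.clip(np.floor(x / unit + 0.5).astype(int), 0, None)
    open_mask = levels >= 1

    # run-length encode the open/closed mask, drop short open runs
    padded = np.diff(np.concatenate(([0], open_mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    min_samples = max(int(round(min_dwell_s * fs)), 1)

    events: list[ChannelEvent] = []
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < min_samples:
            continue
        # split the open segment at *sustained* level boundaries: brief
        # excursions (noise/jitter across a level threshold) shorter than
        # min_dwell are absorbed into the neighbouring level
        seg_levels = _stabilize_levels(levels[i0:i1], min_samples)
        change = np.flatnonzero(np.diff(seg_levels)) + 1
        bounds = np.concatenate(([0], change, [i1 - i0]))
        for j0, j1 in zip(bounds[:-1], bounds[1:]):
            amp = float(np.mean(seg[i0 + j0 : i0 + j1]))
            events.append(
                ChannelEvent(
                    start_s=epoch.start_s + (i0 + j0) / fs,
                    dwell_s=(j1 - j0) / fs,
                    amplitude_pa=amp,
                    level=int(seg_levels[j0]),
                )
            )
    return EventList(events, epoch.voltage_mv, epoch.duration_s)


def dwell_time_stats(events: EventList) -> dict:
    """Mean/median/99th-percentile open dwell and event count.

    Emits a warning below 300 events, the minimum the amplitude-histogram
    stage assumes for stable mixture fits.
    """
    if len(events) == 0:
        raise ValueError("event list is empty")
    dwells = events.dwells
    if len(events) < 300:
        warnings.warn(
            f"only {len(events)} events; histogram statistics assume >= 300",
            stacklevel=2,
        )
    return {
        "n_events": len(events),
        "mean_dwell_s": float(np.mean(dwells)),
        "median_dwell_s": float(np.median(dwells)),
        "p99_dwell_s": float(np.percentile(dwells, 99)),
        "open_probability": events.open_probability,
    }
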