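"""Matplotlib figures for the main analysis products."""

from __future__ import annotations

import numpy as np

from .amplitudes import GVCurve, MixtureFit
from .modifiers import Thermogram
from .trace import CurrentTrace


def plot_trace(trace: CurrentTrace, ax=None, max_points: int = 200_000):
    """Current vs time; decimated for very long records."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t, y = trace.time, trace.samples
    if len(t) > max_points:
        stride = len(t) // max_points
        t, y = t[::stride], y[::stride]
    ax.plot(t, y, lw=0.5, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (pA)")
    for ep in trace.protocol:
        ax.axvline(ep.start_s, color="0.7", lw=0.5)
    return ax


def plot_histogram_fit(fit: MixtureFit, ax=None):
    """Amplitude histogram with the fitted Gaussian components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    hist = fit.histogram
    if hist is None:
        raise ValueError("fit carries no histogram")
    ax.bar(hist.centers, hist.counts, width=hist.bin_width, color="0.8", edgecolor="0.5")
    xs = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
    total = np.zeros_like(xs)
    for c in fit.components:
        ys = (
            c.area
            * hist.bin_width
            / (c.sd_pa * np.sqrt(2 * np.pi))
            * np.exp(-((xs - c.mean_pa) ** 2) / (2 * c.sd_pa**2))
        )
        total += ys
        ax.plot(xs, ys, "--", lw=1)
    ax.plot(xs, total, "r-", lw=1.5)
    ax.set_xlabel("amplitude (pA)")
    ax.set_ylabel("count")
    return ax


def plot_gv_curve(curve: GVCurve, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, grp in curve.points.groupby("substate"):
        ax.errorbar(
            grp["voltage_mV"], grp["conductance_pS"], yerr=grp["se_pS"],
            marker="o", ls="-", capsize=3, label=str(label),
        )
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("conductance (pS)")
    ax.legend()
    return ax


def plot_thermogram(scan: Thermogram, ax=None, label: str | None = None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(scan.temperature_c, scan.excess_cp, lw=1, label=label)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("excess heat capacity (a.u.)")
    if label:
        ax.legend()
    return ax
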