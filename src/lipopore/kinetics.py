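"""Macroscopic relaxation kinetics and dose-response cooperativity.

After a voltage step the multichannel current relaxes as a sum of
exponentials: a double-exponential decay at positive voltage (fast and slow
components) and a single-exponential growth after the switch to negative
voltage.  The instantaneous drop of the absolute current at the sign switch
— channel numbers cannot change instantaneously, so the drop reports the
substate conductance ratio — is measured by extrapolating local fits on
both sides of the switch to the switch instant.

The apparent oligomerization order of pore formation comes from the slope
of log10(steady-state current) against log10(lipopeptide concentration);
a slope of 2 indicates that (at least) dimers build the conductive unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import curve_fit

from .idealize import filter_rise_time_s
from .trace import CurrentTrace


@dataclass
class RelaxationFit:
    """offset + sum_i a_i exp(-t/tau_i), taus sorted ascending."""

    amplitudes_pa: np.ndarray
    taus_s: np.ndarray
    offset_pa: float
    amplitude_ses: np.ndarray
    tau_ses: np.ndarray
    offset_se: float
    residual_rms_pa: float
    n_obs: int
    converged: bool = True
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return len(self.taus_s)

    @property
    def tau_fast_s(self) -> float:
        return float(self.taus_s[0])

    @property
    def tau_slow_s(self) -> float:
        return float(self.taus_s[-1])

    @property
    def ssr(self) -> float:
        return self.residual_rms_pa**2 * self.n_obs

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset_pa)
        for a, tau in zip(self.amplitudes_pa, self.taus_s):
            out += a * np.exp(-t / tau)
        return out

    def summary(self) -> str:
        lines = [
            f"{self.n_components}-exponential relaxation fit"
            + ("" if self.converged else "  [NOT CONVERGED]")
            + ("  [degenerate time constants]" if self.degenerate else ""),
            f"  offset = {self.offset_pa:.3f} +/- {self.offset_se:.3f} pA",
        ]
        for i, (a, tau, ase, tse) in enumerate(
            zip(self.amplitudes_pa, self.taus_s, self.amplitude_ses, self.tau_ses)
        ):
            lines.append(
                f"  component {i + 1}: a = {a:.3f} +/- {ase:.3f} pA, "
                f"tau = {tau:.4f} +/- {tse:.4f} s"
            )
        lines.append(f"  residual rms = {self.residual_rms_pa:.4f} pA over {self.n_obs} samples")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "offset_pA": self.offset_pa,
            "offset_se_pA": self.offset_se,
            "amplitudes_pA": list(map(float, self.amplitudes_pa)),
            "amplitude_ses_pA": list(map(float, self.amplitude_ses)),
            "taus_s": list(map(float, self.taus_s)),
            "tau_ses_s": list(map(float, self.tau_ses)),
            "residual_rms_pA": self.residual_rms_pa,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


def _peel_initial(t: np.ndarray, r: np.ndarray, n: int) -> list[tuple[float, float]]:
    """Log-linear peeling initialisation: [(a_slow, tau_slow), ... fast]."""
    comps: list[tuple[float, float]] = []
    resid = r.copy()
    span = t[-1] - t[0]
    for i in range(n):
        sign = 1.0 if np.mean(resid[: max(len(resid) // 10, 2)]) >= 0 else -1.0
        y = sign * resid
        mask = y > max(np.max(y) * 0.02, 1e-12)
        if mask.sum() < 3:
            comps.append((sign * max(np.max(y), 1e-9), span / (2.0 ** (i + 1))))
            continue
        # the slowest remaining component dominates the tail
        tt, yy = t[mask], np.log(y[mask])
        tail = tt > tt[0] + 0.5 * (tt[-1] - tt[0]) if i < n - 1 else np.ones_like(tt, bool)
        if tail.sum() < 3:
            tail = np.ones_like(tt, bool)
        slope, intercept = np.polyfit(tt[tail], yy[tail], 1)
        tau = -1.0 / slope if slope < 0 else span
        a = sign * math.exp(intercept)
        comps.append((a, tau))
        resid = resid - a * np.exp(-t / tau)
    return comps


class RelaxationModel:
    """Multi-exponential model of one relaxation segment.

    ``fit(n_components)`` does a nonlinear least-squares fit of
    offset + sum a_i exp(-t/tau_i), initialised by log-linear peeling.
    The number of components is the caller's choice; use
    :func:`compare_relaxation_fits` for a residual F-test between nestings.
    """

    def __init__(self, time_s: np.ndarray, current_pa: np.ndarray):
        self.t = np.asarray(time_s, dtype=float)
        self.y = np.asarray(current_pa, dtype=float)
        if len(self.t) != len(self.y):
            raise ValueError("time and current must have equal length")
        if len(self.t) < 10:
            raise ValueError("segment too short to fit")
        self.t = self.t - self.t[0]  # time origin at the switch instant

    @classmethod
    def from_trace(
        cls, trace: CurrentTrace, epoch_index: int, guard_s: float | None = None
    ) -> "RelaxationModel":
        """Extract one epoch, resetting the time origin to the switch.

        The first ``guard_s`` seconds (default 2x the filter rise time when
        a cutoff is recorded, else 0) are excluded as a capacitive-transient
        guard.
        """
        epoch = trace.protocol[epoch_index]
        sl = trace.epoch_slice(epoch)
        t = trace.time[sl] - epoch.start_s
        y = trace.samples[sl]
        if guard_s is None:
            cutoff = trace.metadata.get("filter_cutoff_hz")
            guard_s = 2.0 * filter_rise_time_s(cutoff) if cutoff else 0.0
        keep = t >= guard_s
        return cls(t[keep], y[keep])

    def fit(self, n_components: int = 2) -> RelaxationFit:
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        t, y = self.t, self.y
        # tail mean as the offset guess (segment should span ~3 slow taus)
        offset0 = float(np.mean(y[-max(len(y) // 20, 2):]))
        r0 = y - offset0
        comps0 = _peel_initial(t, r0, n_components)

        def model(tt, *p):
            out = np.full_like(tt, p[0])
            for i in range(n_components):
                out = out + p[1 + 2 * i] * np.exp(-tt / p[2 + 2 * i])
            return out

        p0 = [offset0]
        lower = [-np.inf]
        upper = [np.inf]
        tmax = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
        dt = float(np.median(np.diff(t)))
        for a, tau in comps0:
            p0 += [a, float(np.clip(tau, dt, 10 * tmax))]
            lower += [-np.inf, dt / 10.0]
            upper += [np.inf, 100.0 * tmax]
        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, bounds=(lower, upper), maxfev=20000)
            converged = True
        except RuntimeError:
            popt, pcov = np.asarray(p0), np.full((len(p0), len(p0)), np.nan)
            converged = False
        perr = np.sqrt(np.abs(np.diag(pcov)))

        amps = popt[1::2]
        taus = popt[2::2]
        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        aerr, terr = perr[1::2][order], perr[2::2][order]
        resid = y - model(t, *popt)
        degenerate = bool(
            n_components == 2 and abs(taus[1] - taus[0]) < 0.05 * taus[1]
        )
        return RelaxationFit(
            amplitudes_pa=amps,
            taus_s=taus,
            offset_pa=float(popt[0]),
            amplitude_ses=aerr,
            tau_ses=terr,
            offset_se=float(perr[0]),
            residual_rms_pa=float(np.sqrt(np.mean(resid**2))),
            n_obs=len(y),
            converged=converged,
            degenerate=degenerate,
        )


def fit_relaxation(
    time_s: np.ndarray, current_pa: np.ndarray, n_components: int = 2
) -> RelaxationFit:
    """Nonlinear LS fit of offset + sum of exponentials to one segment."""
    return RelaxationModel(time_s, current_pa).fit(n_components)


def compare_relaxation_fits(simple: RelaxationFit, complex_: RelaxationFit) -> float:
    """Residual F-test p-value for adding exponential components."""
    df1 = 2 * (complex_.n_components - simple.n_components)
    df2 = complex_.n_obs - (1 + 2 * complex_.n_components)
    if df1 <= 0 or df2 <= 0:
        raise ValueError("fits are not properly nested")
    f = ((simple.ssr - complex_.ssr) / df1) / (complex_.ssr / df2)
    return float(stats.f.sf(f, df1, df2))


def _extrapolate_to(t: np.ndarray, y: np.ndarray, t_target: float) -> float:
    """Local exponential extrapolation with a linear fallback."""
    tt = t - t[0]
    mean = float(np.mean(y))
    try:
        def single(x, c, a, tau):
            return c + a * np.exp(-x / tau)

        span = max(tt[-1], 1e-9)
        slope = np.polyfit(tt, y, 1)[0]
        p0 = [mean, y[0] - mean if abs(y[0] - mean) > 0 else slope * span, span]
        popt, _ = curve_fit(single, tt, y, p0=p0, maxfev=5000)
        return float(single(t_target - t[0], *popt))
    except (RuntimeError, TypeError, ValueError):
        coef = np.polyfit(tt, y, 1)
        return float(np.polyval(coef, t_target - t[0]))


def jump_ratio(trace: CurrentTrace, switch_time_s: float, window_s: float = 2.0) -> float:
    """Instantaneous |current| ratio across a voltage-sign switch.

    Both sides are extrapolated to the switch instant by a local
    exponential fit over ``window_s``; the returned value is
    |I(switch-)| / |I(switch+)| (1.3 means the absolute current dropped
    1.3-fold at the switch).
    """
    boundaries = {ep.start_s for ep in trace.protocol} | {ep.end_s for ep in trace.protocol}
    if not any(math.isclose(switch_time_s, b, abs_tol=1e-9) for b in boundaries):
        raise ValueError(f"switch_time_s={switch_time_s} is not an epoch boundary")
    inner = [
        b
        for b in boundaries
        if not math.isclose(b, switch_time_s, abs_tol=1e-9)
        and switch_time_s - window_s < b < switch_time_s + window_s
    ]
    if inner:
        raise ValueError("window overlaps another voltage switch; shrink window_s")

    t = trace.time
    pre = (t >= switch_time_s - window_s) & (t < switch_time_s)
    post = (t >= switch_time_s) & (t < switch_time_s + window_s)
    if pre.sum() < 5 or post.sum() < 5:
        raise ValueError("window too short for extrapolation")
    i_pre = _extrapolate_to(t[pre], trace.samples[pre], switch_time_s)
    i_post = _extrapolate_to(t[post], trace.samples[post], switch_time_s)
    if i_post == 0:
        raise ValueError("post-switch current extrapolates to zero")
    return abs(i_pre) / abs(i_post)


@dataclass
class CooperativityFit:
    """Log-log dose-response regression: slope = apparent oligomer order."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        return (
            "log10(I) vs log10(C) regression (OLS)\n"
            f"  slope (oligomerization order) = {self.slope:.3f} +/- {self.slope_se:.3f}\n"
            f"  intercept = {self.intercept:.3f}\n"
            f"  R^2 = {self.r_squared:.5f}   points = {self.n_points}"
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


class CooperativityModel:
    """OLS of log10(steady-state current) on log10(concentration)."""

    def __init__(self, concentration_um: np.ndarray, current_pa: np.ndarray):
        c = np.asarray(concentration_um, dtype=float)
        i = np.asarray(current_pa, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(i <= 0):
            raise ValueError("currents must be positive (log undefined)")
        if len(np.unique(c)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        self.c, self.i = c, i

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "CooperativityModel":
        return cls(table["concentration_uM"].to_numpy(), table["current_pA"].to_numpy())

    def fit(self) -> CooperativityFit:
        x = np.log10(self.c)
        y = np.log10(self.i)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return CooperativityFit(
            slope=float(res.params[1]),
            slope_se=float(res.bse[1]),
            intercept=float(res.params[0]),
            r_squared=float(res.rsquared),
            n_points=len(y),
        )


def fit_cooperativity(table: pd.DataFrame) -> CooperativityFit:
    """Slope of log10 I on log10 C (base-invariant oligomerization order)."""
    return CooperativityModel.from_dataframe(table).fit()
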