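"""Membrane-modifier effects and lipid-melting calorimetry.

Two small analyses accompany the channel work.  First, amphiphilic membrane
modifiers (phloretin, myricetin, RH 421, tetracaine, T3, Triton X-100,
caffeine) change the lipopeptide-induced steady-state conductance; their
effect on the membrane boundary potential is read from the conductance of a
nonactin-doped bilayer through the Boltzmann relation

    delta_phi_b = (kT/e) * ln(G_m / G_m0),

where G_m and G_m0 are the nonactin conductances with and without the
modifier.  Positive delta_phi_b means the boundary potential increased; the
dipole modifiers that *reduce* the potential (phloretin, T3) therefore give
negative values, reported here signed.

Second, differential scanning calorimetry of DPPC liposomes: the analysis
extracts the main-transition temperature T_m, the full width at half
maximum of the main peak (the cooperativity proxy, here called the
half-width delta_T_1/2), and the pre-transition, from excess heat capacity
vs temperature scans.  A melting-point depression is reported as a positive
delta_T_m relative to the control scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ROOM_TEMPERATURE_K, thermal_voltage_mv


def conductance_ratio(i_after_pa: float, i_before_pa: float) -> float:
    """|I_after / I_before| at fixed voltage (G_modifier/G_control)."""
    if i_before_pa == 0:
        raise ValueError("baseline current must be nonzero")
    if i_after_pa == 0:
        raise ValueError("modified current must be nonzero")
    if i_after_pa * i_before_pa < 0:
        raise ValueError("currents must have the same sign (same voltage)")
    return abs(i_after_pa / i_before_pa)


def boundary_potential_shift(
    gm_ps: float, gm0_ps: float, temperature_k: float = ROOM_TEMPERATURE_K
) -> float:
    """Boundary-potential change from a nonactin conductance pair, mV.

    delta_phi_b = (kT/e) ln(G_m/G_m0); 25.69 mV per e-fold at 298.15 K.
    """
    if gm_ps <= 0 or gm0_ps <= 0:
        raise ValueError("conductances must be positive")
    return thermal_voltage_mv(temperature_k) * math.log(gm_ps / gm0_ps)


@dataclass
class Thermogram:
    """Excess heat capacity (a.u.) vs temperature (degC) on a strict grid."""

    temperature_c: np.ndarray
    excess_cp: np.ndarray

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.excess_cp = np.asarray(self.excess_cp, dtype=float)
        if len(self.temperature_c) != len(self.excess_cp):
            raise ValueError("temperature and heat-capacity arrays differ in length")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (np.all(np.isfinite(self.temperature_c)) and np.all(np.isfinite(self.excess_cp))):
            raise ValueError("thermogram values must be finite")

    @property
    def step_c(self) -> float:
        return float(np.median(np.diff(self.temperature_c)))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"temperature_C": self.temperature_c, "excess_cp": self.excess_cp}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Thermogram":
        df = pd.read_csv(path, comment="#")
        return cls(df["temperature_C"].to_numpy(), df["excess_cp"].to_numpy())


@dataclass
class ThermoResult:
    """Extracted phase-transition parameters of one scan."""

    t_m_c: float | None
    t_half_width_c: float | None
    t_pre_c: float | None = None
    delta_t_m_c: float | None = None
    delta_t_half_c: float | None = None
    peak_height: float | None = None
    ok: bool = True

    def to_dict(self) -> dict:
        return {
            "T_m_C": self.t_m_c,
            "delta_T_half_width_C": self.t_half_width_c,
            "T_pre_C": self.t_pre_c,
            "delta_T_m_C": self.delta_t_m_c,
            "delta_T_half_change_C": self.delta_t_half_c,
            "peak_height": self.peak_height,
            "ok": self.ok,
        }


def _parabolic_apex(x: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    """Refine a grid maximum by a local quadratic through three points."""
    if k <= 0 or k >= len(y) - 1:
        return float(x[k]), float(y[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[k]), float(y[k])
    frac = 0.5 * (y0 - y2) / denom
    step = x[k + 1] - x[k]
    return float(x[k] + frac * step), float(y1 - 0.25 * (y0 - y2) * frac)


def _fwhm(x: np.ndarray, y: np.ndarray, k_peak: int, height: float) -> float | None:
    """Full width at half maximum around the peak at index ``k_peak``."""
    half = height / 2.0
    left = None
    for i in range(k_peak, 0, -1):
        if y[i - 1] <= half <= y[i]:
            left = x[i - 1] + (x[i] - x[i - 1]) * (half - y[i - 1]) / (y[i] - y[i - 1])
            break
    right = None
    for i in range(k_peak, len(y) - 1):
        if y[i + 1] <= half <= y[i]:
            right = x[i] + (x[i + 1] - x[i]) * (y[i] - half) / (y[i] - y[i + 1])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def analyze_thermogram(
    scan: Thermogram,
    control: Thermogram | None = None,
    pre_transition_min_fraction: float = 0.05,
) -> ThermoResult:
    """Extract T_m, the main-peak half-width and the pre-transition.

    A linear baseline anchored at the scan endpoints is subtracted.  The
    main transition is the global maximum, refined off-grid by a local
    parabola; its half-width is the full width at half the corrected peak
    height.  The pre-transition is the largest secondary maximum below T_m
    exceeding ``pre_transition_min_fraction`` of the main height.  With a
    control scan, delta_T_m = T_m(control) - T_m(sample) (positive =
    melting-point depression) and the half-width change is sample minus
    control (positive = broadening, i.e. lost cooperativity).
    """
    temp = scan.temperature_c
    # endpoint-anchored linear baseline (mean of 5 points at each end)
    m = min(5, len(temp) // 10 + 1)
    x0, y0 = float(np.mean(temp[:m])), float(np.mean(scan.excess_cp[:m]))
    x1, y1 = float(np.mean(temp[-m:])), float(np.mean(scan.excess_cp[-m:]))
    slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
    corrected = scan.excess_cp - (y0 + slope * (temp - x0))

    noise = float(
        np.median(np.abs(np.diff(corrected) - np.median(np.diff(corrected))))
        / 0.67448975
        / math.sqrt(2.0)
    )
    k = int(np.argmax(corrected))
    if corrected[k] <= max(5.0 * noise, 0.0) or corrected[k] <= 0:
        return ThermoResult(None, None, ok=False)

    t_m, height = _parabolic_apex(temp, corrected, k)
    width = _fwhm(temp, corrected, k, height)

    # pre-transition: largest local maximum below the main peak's half-width
    # region, above the detectability floor
    t_pre = None
    from scipy.signal import find_peaks

    exclusion = (width or scan.step_c) * 2.0
    idx, _ = find_peaks(corrected, height=pre_transition_min_fraction * height)
    candidates = [i for i in idx if temp[i] < t_m - exclusion]
    if candidates:
        best = max(candidates, key=lambda i: corrected[i])
        t_pre, _ = _parabolic_apex(temp, corrected, best)

    result = ThermoResult(
        t_m_c=t_m, t_half_width_c=width, t_pre_c=t_pre, peak_height=height
    )
    if control is not None:
        ctrl = analyze_thermogram(control)
        if ctrl.ok and ctrl.t_m_c is not None:
            result.delta_t_m_c = ctrl.t_m_c - t_m
            if width is not None and ctrl.t_half_width_c is not None:
                result.delta_t_half_c = width - ctrl.t_half_width_c
    return result


@dataclass(frozen=True)
class ModifierEffect:
    """One row of a modifier panel: conductance ratio and potential shift."""

    name: str
    g_ratio: float
    delta_phi_b_mv: float | None = None


def modifier_panel(
    table: pd.DataFrame, temperature_k: float = ROOM_TEMPERATURE_K
) -> list[ModifierEffect]:
    """Evaluate a CSV-style panel (name,i_before_pA,i_after_pA[,gm_pS,gm0_pS])."""
    effects = []
    for _, row in table.iterrows():
        ratio = conductance_ratio(row["i_after_pA"], row["i_before_pA"])
        shift = None
        if "gm_pS" in row and "gm0_pS" in row and pd.notna(row["gm_pS"]):
            shift = boundary_potential_shift(row["gm_pS"], row["gm0_pS"], temperature_k)
        effects.append(ModifierEffect(str(row["name"]), ratio, shift))
    return effects
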