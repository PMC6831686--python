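"""Ion selectivity from reversal potentials in KCl gradients.

For a channel bathed in asymmetric KCl, the zero-current (reversal)
potential relates to the cation transfer number t+ (the fraction of current
carried by K+) through

    V_rev = (kT/e) (1 - 2 t+) ln(a_cis / a_trans),

with a = gamma * C the mean ionic activity on each side.  t+ = 0.5 means no
selectivity; t+ = 1, ideal cation selectivity (the Nernst limit).  Voltage
is cis relative to trans, so with the standard 2 M cis / 0.2 M trans
gradient a negative reversal potential signals cation selectivity.

Mean molar activity coefficients of KCl at 25 degC are embedded below
(Robinson & Stokes, "Electrolyte Solutions", 2nd ed., Appendix 8.10 — the
standard isopiestic reference table) and interpolated log-linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import ROOM_TEMPERATURE_K, thermal_voltage_mv

# KCl mean activity coefficients at 25 degC; concentration in mol/L.
_KCL_GAMMA_TABLE = (
    (0.001, 0.965),
    (0.002, 0.951),
    (0.005, 0.927),
    (0.01, 0.902),
    (0.02, 0.869),
    (0.05, 0.817),
    (0.1, 0.770),
    (0.2, 0.718),
    (0.3, 0.688),
    (0.5, 0.649),
    (0.7, 0.626),
    (1.0, 0.604),
    (1.5, 0.583),
    (2.0, 0.573),
    (3.0, 0.569),
    (4.0, 0.577),
)
_LOG_C = np.log([c for c, _ in _KCL_GAMMA_TABLE])
_LOG_G = np.log([g for _, g in _KCL_GAMMA_TABLE])


def kcl_mean_activity_coefficient(concentration_m: float) -> float:
    """Mean activity coefficient of aqueous KCl at 25 degC.

    Log-linear interpolation in the embedded reference table.  Below the
    0.001 M table edge the value is extrapolated toward the infinite-
    dilution limit and clamped at 1; concentrations above 4 M are rejected.
    """
    c = float(concentration_m)
    if c <= 0:
        raise ValueError(f"concentration must be positive, got {c}")
    if c > 4.0:
        raise ValueError(f"concentration {c} M outside the tabulated range (<= 4 M)")
    if c < _KCL_GAMMA_TABLE[0][0]:
        slope = (_LOG_G[1] - _LOG_G[0]) / (_LOG_C[1] - _LOG_C[0])
        lg = _LOG_G[0] + slope * (math.log(c) - _LOG_C[0])
        return min(math.exp(lg), 1.0)
    return float(min(math.exp(np.interp(math.log(c), _LOG_C, _LOG_G)), 1.0))


@dataclass(frozen=True)
class SelectivityMeasurement:
    """One reversal-potential measurement under a KCl gradient.

    Activity coefficients default to the embedded 25 degC KCl table.
    """

    v_rev_mv: float
    c_cis_m: float
    c_trans_m: float
    gamma_cis: float | None = None
    gamma_trans: float | None = None
    temperature_k: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.c_cis_m <= 0 or self.c_trans_m <= 0:
            raise ValueError("concentrations must be positive")
        for g in (self.gamma_cis, self.gamma_trans):
            if g is not None and not (0 < g <= 1.2):
                raise ValueError(f"activity coefficient out of range: {g}")

    @property
    def activity_cis(self) -> float:
        g = self.gamma_cis or kcl_mean_activity_coefficient(self.c_cis_m)
        return g * self.c_cis_m

    @property
    def activity_trans(self) -> float:
        g = self.gamma_trans or kcl_mean_activity_coefficient(self.c_trans_m)
        return g * self.c_trans_m


@dataclass(frozen=True)
class SelectivityResult:
    """Cation/anion transfer numbers; t+ + t- = 1 by definition."""

    t_plus: float
    t_minus: float

    def to_dict(self) -> dict:
        return {"t_plus": self.t_plus, "t_minus": self.t_minus}


def transfer_number_from_vrev(m: SelectivityMeasurement) -> SelectivityResult:
    """Invert the reversal-potential relation for the transfer number.

    t+ = (1 - V_rev * e / (kT * ln(a_cis/a_trans))) / 2.
    """
    a1, a2 = m.activity_cis, m.activity_trans
    if math.isclose(a1, a2, rel_tol=1e-12):
        raise ValueError("equal activities on both sides: t+ is undefined")
    vt = thermal_voltage_mv(m.temperature_k)
    t_plus = 0.5 * (1.0 - m.v_rev_mv / (vt * math.log(a1 / a2)))
    return SelectivityResult(t_plus=t_plus, t_minus=1.0 - t_plus)


def vrev_from_transfer_number(
    t_plus: float,
    c_cis_m: float,
    c_trans_m: float,
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> float:
    """Reversal potential (mV) for a given cation transfer number."""
    if not (0.0 <= t_plus <= 1.0):
        raise ValueError(f"t_plus must be in [0, 1], got {t_plus}")
    a1 = kcl_mean_activity_coefficient(c_cis_m) * c_cis_m
    a2 = kcl_mean_activity_coefficient(c_trans_m) * c_trans_m
    vt = thermal_voltage_mv(temperature_k)
    return vt * (1.0 - 2.0 * t_plus) * math.log(a1 / a2)


@dataclass
class VrevActivityFit:
    """OLS of V_rev on ln(a_cis/a_trans): slope estimates (kT/e)(1-2t+)."""

    slope_mv: float
    slope_se_mv: float
    intercept_mv: float
    r_squared: float
    temperature_k: float = ROOM_TEMPERATURE_K

    @property
    def t_plus(self) -> float:
        return 0.5 * (1.0 - self.slope_mv / thermal_voltage_mv(self.temperature_k))

    @property
    def t_plus_se(self) -> float:
        return 0.5 * self.slope_se_mv / thermal_voltage_mv(self.temperature_k)

    def summary(self) -> str:
        return (
            "V_rev vs ln activity ratio (OLS)\n"
            f"  slope     = {self.slope_mv:.3f} +/- {self.slope_se_mv:.3f} mV per ln-unit\n"
            f"  intercept = {self.intercept_mv:.3f} mV\n"
            f"  R^2       = {self.r_squared:.5f}\n"
            f"  implied t+ = {self.t_plus:.3f} +/- {self.t_plus_se:.3f}"
        )


def vrev_activity_regression(
    points: pd.DataFrame | list[tuple[float, float, float]],
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> VrevActivityFit:
    """Linearity check of V_rev against the log activity ratio.

    ``points`` rows are (v_rev_mV, a_cis, a_trans).  A straight line with
    slope (kT/e)(1-2t+) confirms that the ionic strength does not reshape
    the selectivity filter across the gradient series.
    """
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["v_rev_mV", "a_cis", "a_trans"])
    if len(points) < 3:
        raise ValueError("need at least 3 gradient points")
    x = np.log(points["a_cis"].to_numpy() / points["a_trans"].to_numpy())
    y = points["v_rev_mV"].to_numpy()
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return VrevActivityFit(
        slope_mv=float(res.params[1]),
        slope_se_mv=float(res.bse[1]),
        intercept_mv=float(res.params[0]),
        r_squared=float(res.rsquared),
        temperature_k=temperature_k,
    )
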