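"""Voltage dependence of the open-channel number: Boltzmann-quadratic fit.

The effective number of open channels N_ch(V) — macroscopic conductance
divided by the single-channel conductance of the most frequently observed
substate — follows a Boltzmann distribution over the excess channel-
formation work W_ch(V) - W_ch(0).  That work contains a Coulomb term with
effective gating charge q and an electrostriction term quadratic in the
voltage, giving in the reduced potential u = eV/kT

    ln N_ch(V) = ln N_ch(0) + q u + alpha' u^2,

an ordinary least-squares problem.  alpha' is the dimensionless
electrostriction constant (alpha' = alpha kT/e^2 with alpha in J/V^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import (
    BOLTZMANN_J_PER_K,
    ELEMENTARY_CHARGE_C,
    ROOM_TEMPERATURE_K,
    dimensionless_voltage,
)


def effective_channel_number(g_macro_ps: float, g_single_ps: float) -> float:
    """Quasi-steady-state macroscopic conductance over single-channel amplitude.

    Returns the (possibly non-integer) effective number of simultaneously
    open channels; substate heterogeneity is deliberately ignored — the
    dominant substate's conductance is the divisor.
    """
    if g_macro_ps <= 0 or g_single_ps <= 0:
        raise ValueError("conductances must be positive")
    return g_macro_ps / g_single_ps


@dataclass(frozen=True)
class ChannelCountPoint:
    """One voltage point of the ln N_ch vs u data set."""

    voltage_mv: float
    n_ch: float
    temperature_k: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.n_ch <= 0:
            raise ValueError("n_ch must be positive")

    @property
    def u(self) -> float:
        return float(dimensionless_voltage(self.voltage_mv, self.temperature_k))

    @classmethod
    def from_conductances(
        cls,
        voltage_mv: float,
        g_macro_ps: float,
        g_single_ps: float,
        temperature_k: float = ROOM_TEMPERATURE_K,
    ) -> "ChannelCountPoint":
        return cls(voltage_mv, effective_channel_number(g_macro_ps, g_single_ps), temperature_k)


@dataclass
class GatingFitResults:
    """Estimates of (N_ch(0), q, alpha') with their ln-space covariance."""

    n0: float
    q: float
    alpha_prime: float
    cov: np.ndarray  # covariance of (ln n0, q, alpha')
    temperature_k: float
    r_squared: float
    n_points: int

    @property
    def ln_n0_se(self) -> float:
        return float(math.sqrt(self.cov[0, 0]))

    @property
    def n0_se(self) -> float:
        # delta method on n0 = exp(ln n0)
        return self.n0 * self.ln_n0_se

    @property
    def q_se(self) -> float:
        return float(math.sqrt(self.cov[1, 1]))

    @property
    def alpha_prime_se(self) -> float:
        return float(math.sqrt(self.cov[2, 2]))

    @property
    def alpha_si(self) -> float:
        """Electrostriction constant alpha in J/V^2 (alpha' e^2 / kT)."""
        kt = BOLTZMANN_J_PER_K * self.temperature_k
        return self.alpha_prime * ELEMENTARY_CHARGE_C**2 / kt

    def work_excess_kt(self, voltage_mv: float) -> float:
        """W_ch(V) - W_ch(0) in kT units: -q u - alpha' u^2 (zero at V = 0)."""
        u = float(dimensionless_voltage(voltage_mv, self.temperature_k))
        return -self.q * u - self.alpha_prime * u**2

    def predict_n_ch(self, voltage_mv) -> np.ndarray:
        u = np.asarray(dimensionless_voltage(np.asarray(voltage_mv, dtype=float), self.temperature_k))
        return self.n0 * np.exp(self.q * u + self.alpha_prime * u**2)

    def summary(self) -> str:
        return (
            "Boltzmann-quadratic voltage-gating fit (OLS on ln N_ch)\n"
            f"  N_ch(0) = {self.n0:.1f} +/- {self.n0_se:.1f}\n"
            f"  q       = {self.q:.4f} +/- {self.q_se:.4f}\n"
            f"  alpha'  = {self.alpha_prime:.4f} +/- {self.alpha_prime_se:.4f}\n"
            f"  R^2 = {self.r_squared:.5f}   points = {self.n_points}   "
            f"T = {self.temperature_k} K"
        )

    def to_dict(self) -> dict:
        return {
            "n0": self.n0,
            "n0_se": self.n0_se,
            "q": self.q,
            "q_se": self.q_se,
            "alpha_prime": self.alpha_prime,
            "alpha_prime_se": self.alpha_prime_se,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "temperature_K": self.temperature_k,
        }


class BoltzmannGatingModel:
    """OLS model of ln N_ch on (1, u, u^2).

    Unweighted by default; per-point weights may be supplied for a WLS fit.
    """

    def __init__(
        self,
        n_ch: Sequence[float],
        u: Sequence[float],
        temperature_k: float = ROOM_TEMPERATURE_K,
        weights: Sequence[float] | None = None,
    ):
        self.n_ch = np.asarray(n_ch, dtype=float)
        self.u = np.asarray(u, dtype=float)
        self.temperature_k = temperature_k
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if np.any(self.n_ch <= 0):
            raise ValueError("all channel counts must be positive")
        if len(self.n_ch) < 4:
            raise ValueError("need at least 4 points")
        if len(np.unique(self.u)) < 3:
            raise ValueError("need at least 3 distinct u values (rank-deficient design)")

    @classmethod
    def from_points(cls, points: Sequence[ChannelCountPoint], **kw) -> "BoltzmannGatingModel":
        temps = {p.temperature_k for p in points}
        if len(temps) > 1:
            raise ValueError("all points must share one temperature")
        return cls(
            [p.n_ch for p in points],
            [p.u for p in points],
            temperature_k=temps.pop(),
            **kw,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temperature_k: float = ROOM_TEMPERATURE_K, **kw
    ) -> "BoltzmannGatingModel":
        """Accepts columns (u, n_ch) or (voltage_mV, n_ch) or conductance pairs."""
        if "n_ch" in df:
            n_ch = df["n_ch"].to_numpy()
        else:
            n_ch = df["g_macro_pS"].to_numpy() / df["g_single_pS"].to_numpy()
        if "u" in df:
            u = df["u"].to_numpy()
        else:
            u = dimensionless_voltage(df["voltage_mV"].to_numpy(), temperature_k)
        return cls(n_ch, u, temperature_k=temperature_k, **kw)

    def fit(self) -> GatingFitResults:
        y = np.log(self.n_ch)
        X = np.column_stack([np.ones_like(self.u), self.u, self.u**2])
        if self.weights is None:
            res = sm.OLS(y, X).fit()
        else:
            res = sm.WLS(y, X, weights=self.weights).fit()
        params = np.asarray(res.params)
        return GatingFitResults(
            n0=float(np.exp(params[0])),
            q=float(params[1]),
            alpha_prime=float(params[2]),
            cov=np.asarray(res.cov_params()),
            temperature_k=self.temperature_k,
            r_squared=float(res.rsquared),
            n_points=len(y),
        )


def fit_boltzmann_quadratic(
    points: Sequence[ChannelCountPoint] | pd.DataFrame,
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> GatingFitResults:
    """Fit ln N_ch = ln N_ch(0) + q u + alpha' u^2 by ordinary least squares."""
    if isinstance(points, pd.DataFrame):
        model = BoltzmannGatingModel.from_dataframe(points, temperature_k)
    else:
        model = BoltzmannGatingModel.from_points(points)
    return model.fit()


def channel_work_excess(fit: GatingFitResults, voltage_mv: float) -> float:
    """Excess channel-formation work W_ch(V) - W_ch(0) in kT units."""
    return fit.work_excess_kt(voltage_mv)
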