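"""Amplitude histograms, Gaussian-mixture fits and conductance-voltage curves.

The single-channel current-amplitude (equivalently current-transition)
histogram at each voltage is decomposed into a sum of normal density
functions.  The number of components K is chosen by a Pearson chi-square
goodness-of-fit rule: the smallest K whose fit is *not* rejected at
alpha = 0.05 (sparse bins pooled to an expected count of at least 5) is
accepted.  The area under each component measures the probability of
observing openings of that amplitude, so the ratio of the areas of the
large- and small-amplitude components quantifies the voltage-sign-dependent
substate preference, and the mean of the dominant (largest-area) component
divided by the voltage gives the conductance of the most frequently
observed channels — the quantity the conductance-voltage curve and the
macroscopic channel-count analysis are built on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .trace import EventList


@dataclass
class AmplitudeHistogram:
    """Binned event amplitudes at one voltage."""

    bin_edges: np.ndarray
    counts: np.ndarray
    voltage_mv: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/edges length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.bin_edges)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_pA": self.bin_edges[:-1],
                "bin_right_pA": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def robust_sd(x: np.ndarray) -> float:
    """MAD-based standard-deviation estimate."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.67448975)


def build_histogram(
    events: EventList | np.ndarray,
    bin_width_pa: float | None = None,
    voltage_mv: float | None = None,
) -> AmplitudeHistogram:
    """Histogram of event amplitudes.

    The default bin width is 2 * (robust amplitude sd) / sqrt(n): bins
    resolve peak positions at roughly the precision of a component-mean
    estimate while keeping expected counts near the peaks comfortably above
    the chi-square pooling threshold.
    """
    if isinstance(events, EventList):
        amps = events.amplitudes
        if voltage_mv is None:
            voltage_mv = events.voltage_mv
    else:
        amps = np.asarray(events, dtype=float)
    n = len(amps)
    if n < 50:
        raise ValueError(f"need at least 50 events to build a histogram, got {n}")
    if n < 300:
        warnings.warn(
            f"only {n} events; amplitude statistics assume 300-900", stacklevel=2
        )
    if bin_width_pa is None:
        sd = robust_sd(amps)
        if sd == 0:
            sd = max(abs(float(np.mean(amps))) * 1e-3, 1e-6)
        bin_width_pa = 2.0 * sd / math.sqrt(n)
    if bin_width_pa <= 0:
        raise ValueError(f"bin_width_pa must be positive, got {bin_width_pa}")
    lo = amps.min() - bin_width_pa / 2.0
    nbins = int(np.ceil((amps.max() - lo) / bin_width_pa)) + 1
    edges = lo + bin_width_pa * np.arange(nbins + 1)
    counts, _ = np.histogram(amps, bins=edges)
    return AmplitudeHistogram(edges, counts, voltage_mv)


@dataclass
class MixtureComponent:
    mean_pa: float
    sd_pa: float
    area: float
    mean_se: float = float("nan")
    area_se: float = float("nan")


@dataclass
class MixtureFit:
    """Sum-of-Gaussians decomposition of an amplitude histogram.

    ``selected`` is False when no K up to the allowed maximum passed the
    chi-square goodness-of-fit rule and the best-fitting K was returned
    instead.
    """

    components: list[MixtureComponent]
    chi2: float
    pvalue: float
    dof: int
    n_total: int
    voltage_mv: float | None = None
    selected: bool = True
    histogram: AmplitudeHistogram | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def total_area(self) -> float:
        return float(sum(c.area for c in self.components))

    @property
    def dominant(self) -> MixtureComponent:
        """Component with the largest area (most frequently observed channels)."""
        return max(self.components, key=lambda c: c.area)

    def predict(self, edges: np.ndarray) -> np.ndarray:
        """Expected counts per bin under the fitted mixture."""
        edges = np.asarray(edges, dtype=float)
        expected = np.zeros(len(edges) - 1)
        for c in self.components:
            cdf = stats.norm.cdf(edges, loc=c.mean_pa, scale=c.sd_pa)
            expected += c.area * np.diff(cdf)
        return expected

    def summary(self) -> str:
        lines = [
            "Gaussian mixture fit of amplitude histogram",
            f"  components: {self.n_components}   events: {self.n_total}"
            + (f"   voltage: {self.voltage_mv} mV" if self.voltage_mv is not None else ""),
            f"  chi2 = {self.chi2:.2f}  dof = {self.dof}  p = {self.pvalue:.3g}"
            + ("" if self.selected else "  [no K passed at alpha=0.05]"),
            "  {:>10} {:>10} {:>10} {:>10}".format("mean_pA", "sd_pA", "area", "mean_SE"),
        ]
        for c in self.components:
            lines.append(
                "  {:>10.4f} {:>10.4f} {:>10.1f} {:>10.4f}".format(
                    c.mean_pa, c.sd_pa, c.area, c.mean_se
                )
            )
        return "\n".join(lines)

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureFit":
        comps = [
            MixtureComponent(
                c["mean_pA"], c["sd_pA"], c["area"],
                c.get("mean_SE", float("nan")), c.get("area_SE", float("nan")),
            )
            for c in payload["components"]
        ]
        return cls(
            comps,
            payload.get("chi2", float("nan")),
            payload.get("pvalue", float("nan")),
            payload.get("dof", 0),
            payload.get("n_total", int(round(sum(c.area for c in comps)))),
            payload.get("voltage_mV"),
            payload.get("selected", True),
        )

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "chi2": self.chi2,
            "pvalue": self.pvalue,
            "dof": self.dof,
            "n_total": self.n_total,
            "voltage_mV": self.voltage_mv,
            "selected": self.selected,
            "components": [
                {
                    "mean_pA": c.mean_pa,
                    "sd_pA": c.sd_pa,
                    "area": c.area,
                    "mean_SE": c.mean_se,
                    "area_SE": c.area_se,
                }
                for c in self.components
            ],
        }


def _weighted_kmeans(centers0: np.ndarray, x: np.ndarray, w: np.ndarray, iters: int = 100) -> np.ndarray:
    """Deterministic Lloyd iterations on weighted points."""
    centers = centers0.copy()
    for _ in range(iters):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for k in range(len(centers)):
            m = assign == k
            if w[m].sum() > 0:
                new[k] = np.average(x[m], weights=w[m])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def _pooled_chi2(observed: np.ndarray, expected: np.ndarray, n_params: int) -> tuple[float, float, int]:
    """Pearson chi-square with adjacent pooling to expected >= 5."""
    obs_p, exp_p = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
            o_acc = e_acc = 0.0
    if exp_p:
        obs_p[-1] += o_acc
        exp_p[-1] += e_acc
    else:
        obs_p, exp_p = [o_acc], [e_acc]
    obs_p = np.asarray(obs_p)
    exp_p = np.asarray(exp_p)
    exp_p = np.where(exp_p <= 0, 1e-9, exp_p)
    chi2 = float(np.sum((obs_p - exp_p) ** 2 / exp_p))
    dof = len(obs_p) - n_params
    pvalue = float(stats.chi2.sf(chi2, dof)) if dof >= 1 else float("nan")
    return chi2, pvalue, dof


class AmplitudeMixtureModel:
    """Sum-of-Gaussians model for an amplitude histogram.

    ``fit()`` performs a bin-integrated least-squares fit for K = 1..max
    components and returns the smallest K not rejected by the chi-square
    goodness-of-fit rule at ``alpha``.  Component standard deviations are
    bounded below by ``sd_floor_pa`` (default half a bin width) to prevent
    spike components.  Initialisation is a deterministic weighted k-means on
    the bin centers; ties resolve to the lowest mean.
    """

    def __init__(self, histogram: AmplitudeHistogram, sd_floor_pa: float | None = None):
        self.histogram = histogram
        self.sd_floor_pa = sd_floor_pa if sd_floor_pa is not None else histogram.bin_width / 2.0

    def _fit_k(self, k: int) -> tuple[list[MixtureComponent], float, float, int] | None:
        hist = self.histogram
        x, w = hist.centers, hist.counts.astype(float)
        occupied = int(np.count_nonzero(w))
        if occupied < 3 * k:
            raise ValueError(
                f"{occupied} occupied bins cannot constrain {3 * k} mixture parameters"
            )
        # deterministic init: quantile-spaced centers refined by k-means
        cum = np.cumsum(w) / w.sum()
        quantiles = (np.arange(k) + 0.5) / k
        centers0 = np.array([x[np.searchsorted(cum, qv)] for qv in quantiles])
        centers = _weighted_kmeans(centers0, x, w)
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        p0, lower, upper = [], [], []
        span = x.max() - x.min() + hist.bin_width
        for j in range(k):
            m = assign == j
            area0 = max(w[m].sum(), 1.0)
            sd0 = robust_sd(np.repeat(x[m], w[m].astype(int))) if w[m].sum() >= 2 else self.sd_floor_pa
            sd0 = max(sd0, self.sd_floor_pa)
            # sd capped at a third of the span: an amplitude substate never
            # legitimately covers the whole histogram, and an unbounded sd
            # lets one near-flat Gaussian swallow any misspecified shape
            sd_cap = max(span / 3.0, 2.0 * self.sd_floor_pa)
            p0 += [centers[j], min(sd0, sd_cap * 0.9), area0]
            lower += [x.min() - span, self.sd_floor_pa, 0.0]
            upper += [x.max() + span, sd_cap, 10.0 * hist.n_total]

        edges = hist.bin_edges

        def model(params):
            out = np.zeros(len(edges) - 1)
            for j in range(k):
                mu, sd, area = params[3 * j : 3 * j + 3]
                out += area * np.diff(stats.norm.cdf(edges, loc=mu, scale=sd))
            return out

        # Poisson maximum likelihood on bin counts: sparse bins carry their
        # correct weight (least squares with count weights is miscalibrated
        # when many expected counts are small)
        def nll(params):
            e = np.maximum(model(params), 1e-12)
            return float(np.sum(e) - np.sum(w * np.log(e)))

        opt = minimize(
            nll, p0, method="L-BFGS-B",
            bounds=list(zip(lower, upper)), options={"maxiter": 2000},
        )
        if not np.all(np.isfinite(opt.x)):
            return None
        popt = opt.x
        # Fisher information: G^T diag(1/E) G with G = dE/dtheta (central diff)
        e_hat = np.maximum(model(popt), 1e-12)
        grad = np.empty((len(e_hat), len(popt)))
        for jp in range(len(popt)):
            h = max(1e-6, 1e-6 * abs(popt[jp]))
            up, dn = popt.copy(), popt.copy()
            up[jp] += h
            dn[jp] -= h
            grad[:, jp] = (model(up) - model(dn)) / (2 * h)
        fisher = grad.T @ (grad / e_hat[:, None])
        pcov = np.linalg.pinv(fisher)
        perr = np.sqrt(np.abs(np.diag(pcov)))
        comps = [
            MixtureComponent(
                mean_pa=float(popt[3 * j]),
                sd_pa=float(popt[3 * j + 1]),
                area=float(popt[3 * j + 2]),
                mean_se=float(perr[3 * j]),
                area_se=float(perr[3 * j + 2]),
            )
            for j in range(k)
        ]
        comps.sort(key=lambda c: c.mean_pa)
        expected = model(popt)
        chi2, pvalue, dof = _pooled_chi2(w, expected, 3 * k)
        return comps, chi2, pvalue, dof

    def fit(self, max_components: int = 3, alpha: float = 0.05) -> MixtureFit:
        if max_components < 1:
            raise ValueError("max_components must be >= 1")
        hist = self.histogram
        best = None
        for k in range(1, max_components + 1):
            res = self._fit_k(k)
            if res is None:
                continue
            comps, chi2, pvalue, dof = res
            fit = MixtureFit(
                comps, chi2, pvalue, dof, hist.n_total, hist.voltage_mv, True, hist
            )
            if dof >= 1 and pvalue > alpha:
                return fit
            if dof < 1 and math.isnan(pvalue):
                # untestable (saturated) fit: accept as selected
                return fit
            if best is None or (not math.isnan(pvalue) and pvalue > best.pvalue):
                best = fit
        if best is None:
            raise ValueError("no mixture size could be fitted to this histogram")
        best.selected = False
        return best


def fit_mixture(hist: AmplitudeHistogram, max_components: int = 3) -> MixtureFit:
    """Fit 1..max_components Gaussians; chi-square rule selects K (see model)."""
    return AmplitudeMixtureModel(hist).fit(max_components)


def substate_ratio(fit: MixtureFit) -> float:
    """Area of the large-amplitude peak over the small-amplitude peak.

    "Large" and "small" are judged by |mean| so the ratio is comparable
    across voltage signs (at negative voltage the large substate has the
    more negative mean).
    """
    if fit.n_components < 2:
        raise ValueError("substate ratio needs at least 2 mixture components")
    comps = sorted(fit.components, key=lambda c: abs(c.mean_pa))
    return comps[-1].area / comps[0].area


@dataclass
class GVCurve:
    """Per-voltage, per-substate single-channel conductances."""

    points: pd.DataFrame  # voltage_mV, conductance_pS, se_pS, n, substate, dominant

    def dominant_conductance(self, voltage_mv: float) -> float:
        df = self.points
        row = df[(df["voltage_mV"] == voltage_mv) & df["dominant"]]
        if row.empty:
            raise KeyError(f"no dominant substate at {voltage_mv} mV")
        return float(row["conductance_pS"].iloc[0])

    def asymmetry_ratio(self, v_num_mv: float, v_den_mv: float) -> float:
        return self.dominant_conductance(v_num_mv) / self.dominant_conductance(v_den_mv)


def gv_curve(per_voltage_fits: list[tuple[float, MixtureFit]]) -> GVCurve:
    """Conductance-voltage curve from per-voltage mixture fits.

    Conductance = component mean / voltage with the pA/mV -> pS scaling
    (x1000); the SE propagates the component sd over sqrt(area).  Substates
    are labelled small/large by |conductance| within each voltage; the
    dominant flag marks the largest-area component.
    """
    if len(per_voltage_fits) < 2:
        raise ValueError("need fits at >= 2 voltages")
    rows = []
    for voltage, fit in per_voltage_fits:
        if voltage == 0:
            raise ValueError("conductance is undefined at 0 mV")
        dom = fit.dominant
        comps = sorted(fit.components, key=lambda c: abs(c.mean_pa))
        for j, c in enumerate(comps):
            g = c.mean_pa / voltage * 1e3
            n = max(c.area, 1.0)
            se = c.sd_pa / math.sqrt(n) / abs(voltage) * 1e3
            label = "small" if j == 0 else ("large" if j == len(comps) - 1 else f"mid{j}")
            if len(comps) == 1:
                label = "only"
            rows.append(
                {
                    "voltage_mV": voltage,
                    "conductance_pS": g,
                    "se_pS": se,
                    "n": n,
                    "substate": label,
                    "dominant": c is dom,
                }
            )
    df = pd.DataFrame(rows)
    if np.any(df["conductance_pS"] <= 0):
        warnings.warn("nonpositive conductance in g-V curve; check component signs", stacklevel=2)
    return GVCurve(df)
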