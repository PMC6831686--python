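# Methods

This note documents the models implemented in `lipopore`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Units and constants

pA for current, mV for voltage, pS for conductance, s for time, K for
temperature; bath concentrations in mol/L, dosing concentrations in µM.
Conductance × voltage uses the pS·mV → pA factor 10⁻³. The thermal voltage
kT/e is 25.693 mV at the default temperature of 298.15 K ("room
temperature"); every formula takes an explicit temperature where it matters.

## Single-channel simulator

The channel is an alternating-renewal two-state process: closed and open
dwells are independent exponentials with means `mean_closed_dwell_s` and
`mean_open_dwell_s`. Each opening is independently assigned to one of two
conductance substates — memoryless per-opening assignment is the simplest
model consistent with two distinguishable amplitude populations; no kinetic
scheme connecting the substates is implied, and sublevels do not
interconvert within one opening. The probability of the large substate is a
function of voltage, by default a logistic centred at 0 mV with a 50 mV
scale, so the large substate dominates at positive potentials, the small one
at negative potentials, and both are comparably likely around ±50 mV.

Parameter defaults and why:

- **Conductances 15 pS (small) and 22 pS (large).** Single-channel
  conductances in the picosiemens range with a ratio ≈ 1.5 reproduce the
  observed asymmetry of the conductance–voltage relation when combined with
  the voltage-dependent substate weights; absolute values are stand-ins
  (configurable), since only the range and the ratio are constrained by
  observation.
- **Mean dwells 40 ms open / 40 ms closed.** Equal means give the observed
  open probability of 0.5. The 40 ms scale is calibrated against the
  observed dwell ceiling: the 99th percentile of an exponential with mean
  40 ms is 184 ms, so realized 60 s records keep their empirical dwell p99
  below 250 ms with margin, including the mild dwell inflation caused by the
  low-pass filter merging sub-resolution closed gaps.
- **Per-opening amplitude jitter (`amplitude_cv` = 0.05).** Without it,
  event amplitudes are segment means whose spread depends on dwell length —
  a strongly non-Gaussian mixture that defeats the Gaussian-mixture
  histogram stage the analysis assumes. A 5% conductance jitter per opening
  emulates the amplitude variability real channel populations show and makes
  the within-substate amplitude distribution approximately Gaussian.
  Noiseless oracle tests set it to 0.
- **Noise.** Additive white Gaussian noise (0.5 pA sd at 5 kHz by default)
  before digital filtering. No 1/f component; a linear baseline drift is
  available as an option for baseline-correction tests.

Sampling defaults to 5 kHz with a 200 Hz analysis filter. The simulator
embeds its true event log in the returned trace; all generators take one
explicit integer seed and touch no global random state.

What the generator does **not** emulate: electrode/amplifier artifacts,
capacitive spikes, membrane rupture, lipid-composition-dependent conductance
physics (compositions are metadata labels), or multi-channel overlaps.
Passing tests therefore demonstrate correctness of the analysis chain under
the stated statistical model, not robustness to instrumentation artifacts.

## Trace preparation and idealization

- **Filter.** Zero-phase Gaussian low-pass with the −3 dB point at the
  cutoff (σ_t = √(ln 2)/(2π f_c)); DC gain exactly 1. The conventional rise
  time is T_r = 0.3321/f_c (reciprocal of the maximum step-response slope);
  the 10–90% rise time is 0.3397/f_c.
- **Baseline.** Per-epoch mode of the all-points histogram
  (Freedman–Diaconis bins, parabolic refinement), subtracted so the closed
  level sits at 0 pA. The mode is the right location estimate while the
  closed level dominates; if no bin clearly dominates, the median is used
  with a warning.
- **Events.** Half-amplitude threshold crossing relative to the supplied
  open-level estimate, which should be the amplitude of the *dominant*
  substate (the multi-level quantization uses it as the unit, so an estimate
  far below the dominant level misassigns levels). Open segments shorter
  than `min_dwell` — default twice the filter rise time, ≈ 3.3 ms at 200 Hz,
  to avoid amplitude bias from attenuated events — are discarded. Within a
  retained segment, brief excursions across a level threshold shorter than
  `min_dwell` are absorbed into the neighbouring level before the segment is
  split at sustained level boundaries; each sub-segment becomes one event
  with its mean current as amplitude.
- **Open probability** is the fraction of epoch time with any conducting
  level (the only definition available without per-channel bookkeeping; at
  the single-channel level the two coincide).

## Amplitude mixtures

Histograms bin event amplitudes with default width 2·σ_robust/√n (σ_robust
from the MAD), resolving peak positions at roughly the precision of a
component-mean estimate. Mixtures of bin-integrated Gaussians are fitted by
Poisson maximum likelihood — with many expected counts below 5, count-
weighted least squares is miscalibrated (the χ² rule then rejects correct
models far above its nominal rate), while Poisson ML restores the nominal
≈ 5% rejection rate. Standard errors come from the Fisher information.

K is selected as the smallest number of components whose Pearson χ²
goodness of fit (adjacent bins pooled to expected ≥ 5, dof = bins − 3K) is
not rejected at α = 0.05; if no K up to the maximum passes, the best K is
returned flagged. Initialisation is a deterministic quantile-seeded weighted
k-means; ties resolve to the lowest mean. Component sd is bounded below by
half a bin width (no spike components) and above by a third of the histogram
span (a single near-flat Gaussian must not absorb a misspecified shape).
"Most frequently observed channels" — used for g(V) and for N_ch — means
the largest-area component at each voltage.

## Selectivity

The transfer-number relation V_rev = (kT/e)(1 − 2t⁺) ln(γ₁C₁/γ₂C₂) is
evaluated with mean molar activity coefficients of aqueous KCl at 25 °C
embedded from the standard isopiestic reference table (Robinson & Stokes,
*Electrolyte Solutions*, 2nd ed.), log-linearly interpolated. Temperature
dependence of γ is neglected (measurements are at room temperature). Below
the 0.001 M table edge the coefficient extrapolates toward, and is clamped
at, the infinite-dilution limit of 1; above 4 M it is out of range.
Voltage is cis minus trans, so a negative V_rev under a cis-heavy gradient
means cation selectivity. The V_rev-vs-ln(a₁/a₂) regression slope estimates
(kT/e)(1 − 2t⁺); no liquid-junction correction and no GHK permeability
formalism are applied.

## Voltage gating and electrostriction

ln N_ch is regressed on (1, u, u²) by unweighted OLS (a weighted variant is
available but off by default, since no weighting scheme is canonical for
these data). N_ch uses the dominant-substate amplitude only; substate
heterogeneity is deliberately ignored in the channel count. The excess
channel-formation work is W_ch(V) − W_ch(0) = −q·u − α′·u² in kT units
(zero at V = 0 by construction), and α = α′e²/kT converts to SI. The
recovery study in the acceptance script uses 9 voltages spanning ±200 mV
with 10% log-normal noise and 100 replicate tables — a documented synthetic
design standing in for the unpublished experimental voltage grid, whose
reported uncertainties it treats as target bands, not exact reproductions.

## Relaxation kinetics and dose response

Multi-exponential fits are initialised by log-linear peeling (tail first)
and refined by bounded nonlinear least squares; time constants are reported
sorted ascending, a two-component fit whose constants agree within 5% is
flagged degenerate, and non-convergence yields a flagged result rather than
an exception. The first 2× filter rise time after a voltage switch is
excluded as a capacitive-transient guard when a filter cutoff is recorded.
An F-test on residual sums of squares compares nested component counts.

The switch jump ratio extrapolates a local single-exponential (linear
fallback) fitted over a short window on each side of the switch to the
switch instant and reports |I(switch⁻)|/|I(switch⁺)|.

The cooperativity slope uses base-10 logs (the slope is base-invariant);
the "close to 2" criterion is implemented in tests as |slope − 2| ≤ 3·SE.

The macroscopic simulator's defaults — decay components of 0.5 s and 6 s
with 2:1 amplitudes, 50 s growth, 1.3-fold instantaneous drop at the
+150 → −150 mV switch — are the experimentally observed time scales; the
steady currents (±1 nA scale) are representative multichannel magnitudes.

## Modifiers and calorimetry

Boundary-potential shifts are computed directly from nonactin conductance
pairs via Δφ_b = (kT/e) ln(G_m/G_m⁰); the nonactin probe itself is
experimental plumbing and is not simulated. The value is reported signed:
negative Δφ_b means the boundary (dipole) potential decreased, as for
phloretin (−70 mV at a conductance ratio of 0.066).

Thermogram analysis subtracts a linear baseline anchored at the scan
endpoints, takes the global maximum as the main transition with a local
parabolic apex refinement (decoupling T_m from the grid step), and measures
ΔT₁/₂ as the full width at half the corrected peak height — consistent with
the 0.5 °C reference half-width of pure DPPC. The pre-transition is the
largest secondary maximum below T_m exceeding 5% of the main height.
Against a control scan, ΔT_m = T_m(control) − T_m(sample), positive for a
melting-point depression, and the half-width change is sample minus control,
positive for broadening (lost cooperativity). Scans with no peak above 5×
the noise floor return a flagged empty result. No multi-component melting
deconvolution and no van't Hoff enthalpy estimation are attempted.

## Problem sizes

Default analysis fixtures are sized for routine laptop runs: 60 s
single-channel records at 5 kHz (~500 openings, within the 300–900 event
range the histogram stage assumes), 30 s + 150 s field-reversal epochs at
100 Hz, 5 concentrations × 3 replicates for dose fits, 9-voltage channel-
count tables with 100 Monte-Carlo replicates, and 0.02 °C thermogram grids.

## Known limitations

- The idealizer is a threshold detector: no hidden-Markov or Viterbi
  idealization, no missed-event correction beyond the explicit `min_dwell`
  cutoff, and no capacitive-spike rejection.
- Event-amplitude distributions from real recordings are only approximately
  Gaussian; the χ² selection rule then tends to flag fits on long fixtures
  even when the two-component decomposition is adequate (the flag, not an
  exception, signals this).
- The two-state gating model has no correlations between adjacent dwells
  and no voltage-dependent dwell times; only substate *weights* depend on
  voltage.
- Activity coefficients are for pure aqueous KCl at 25 °C; buffer
  contributions to ionic strength are neglected.
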