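# lipopore

Quantitative analysis of lipopeptide-induced ion channels in planar lipid
bilayers, built around the pore-forming activity of fengycin — a cyclic
lipopeptide from *Bacillus subtilis* that permeabilizes membranes mimicking
fungal cell membranes (POPC:POPE:POPG:ergosterol). The package is for
membrane biophysicists who record bilayer currents under voltage clamp and
want the complete chain from raw traces to the physical parameters of the
channel, plus a stochastic simulator that generates every input the chain
consumes, so the whole analysis is testable without any recordings.

## What it computes

**Single channels.** Current traces are low-pass filtered (zero-phase
Gaussian, −3 dB at the chosen cutoff), baseline-corrected to pin the closed
level at 0 pA, and idealized by half-amplitude threshold detection into
openings with amplitudes and dwell times. Amplitude histograms are
decomposed into sums of normal densities; the number of components is the
smallest K not rejected by a Pearson χ² goodness-of-fit rule (α = 0.05,
sparse bins pooled). Component areas give the substate probability ratio;
the dominant component's mean over the voltage gives the conductance–voltage
curve g(V).

**Selectivity.** With KCl activities a = γC on the two sides, the reversal
potential obeys

  V_rev = (kT/e)(1 − 2t⁺) ln(a_cis/a_trans),

which is inverted for the cation transfer number t⁺ (t⁻ = 1 − t⁺). Mean
molar activity coefficients of KCl at 25 °C are embedded and interpolated.

**Voltage gating / electrostriction.** The effective number of open
channels, N_ch(V) = G_macro/g_single, follows a Boltzmann distribution over
the excess channel-formation work W_ch(V) − W_ch(0) = −eqV − αV². In the
reduced potential u = eV/kT,

  ln N_ch(V) = ln N_ch(0) + q·u + α′·u²,

fitted by ordinary least squares for the zero-voltage channel number
N_ch(0), the effective gating charge q and the dimensionless
electrostriction constant α′.

**Kinetics and stoichiometry.** Field-reversal relaxations are fitted as
offset + Σ aᵢ·exp(−t/τᵢ) (log-peeling initialisation, nonlinear least
squares); the instantaneous jump of |I| at a voltage-sign switch is measured
by local extrapolation to the switch instant. The apparent oligomerization
order of pore formation is the slope of log₁₀(I∞) vs log₁₀(C).

**Modifiers and calorimetry.** Membrane-modifier effects are summarised by
conductance ratios G_modifier/G_control and by boundary-potential shifts
Δφ_b = (kT/e)·ln(G_m/G_m⁰) from nonactin conductance pairs. DSC thermograms
of DPPC liposomes yield the main transition temperature T_m, the half-width
ΔT₁/₂ of the main peak (cooperativity proxy), the pre-transition, and shifts
ΔT_m, ΔΔT₁/₂ relative to a control scan.

## Worked example

```python
import lipopore as lp

# selectivity: measured V_rev = -35 mV, 2 M cis / 0.2 M trans KCl
sel = lp.transfer_number_from_vrev(lp.SelectivityMeasurement(-35.0, 2.0, 0.2))
print(f"t+ = {sel.t_plus:.3f}, t- = {sel.t_minus:.3f}")

# voltage gating: simulate a noisy channel-count table and refit it
table = lp.simulate_channel_counts(noise_cv=0.1, seed=42)
fit = lp.fit_boltzmann_quadratic(table)
print(fit.summary())

# stoichiometry: dimer-law dose-response with 10% noise, 3 replicates
dose = lp.simulate_dose_response([1, 2, 4, 8, 16], noise_cv=0.1, replicates=3, seed=42)
print(lp.fit_cooperativity(dose).summary())
```

prints

```
t+ = 0.828, t- = 0.172
Boltzmann-quadratic voltage-gating fit (OLS on ln N_ch)
  N_ch(0) = 284.1 +/- 15.5
  q       = -0.0392 +/- 0.0071
  alpha'  = 0.0090 +/- 0.0016
  R^2 = 0.91105   points = 9   T = 298.15 K
log10(I) vs log10(C) regression (OLS)
  slope (oligomerization order) = 1.989 +/- 0.025
  intercept = 1.006
  R^2 = 0.99796   points = 15
```

The transfer number 0.83 means five sixths of the channel current is
carried by K⁺ (weak cation selectivity). The gating fit recovers the
generating parameters (300, −0.037, 0.008) within its standard errors:
~300 channels are open at zero voltage, and both the Coulomb (q·u) and
electrostriction (α′·u²) terms contribute only fractions of kT at ±150 mV —
weakly voltage-gated pores. The dose slope ≈ 2 indicates that at least
dimers build the conductive unit.

The same stages are available from a shell; each subcommand writes JSON
with a full provenance block:

```
lipopore simulate-trace --voltage 150 --duration 60 --seed 1 --out trace.csv
lipopore idealize --trace trace.csv --open-level 2.8 --out events.csv --stats-out stats.json
lipopore report --seed 1 --out report.json
```

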