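# Methods

`sonobubble` models the chain of quantities that determine whether a
clinical ultrasound contrast agent (SonoVue, Sonazoid, Optison) is useful
for low-intensity sonoporation: the acoustic output of the driving pulse,
the radial dynamics of a single encapsulated microbubble, the concentration
of circulating bubbles during a constant-rate infusion, the size statistics
of the bubble population, the attenuation and cavitation signatures
measurable in a water tank, and the mapping from (intensity, concentration)
to the best-performing agent.

## Driving pulses

Pulses are uniformly sampled pressure waveforms p(t) in Pa, compression
positive.  Synthetic tone bursts use a Tukey(0.25) envelope by default: it
suppresses spectral splatter at the burst edges while keeping the stated
peak negative pressure (PNP) over most of the burst; the waveform is scaled
so min p(t) equals −PNP exactly.  A sampling margin of at least 16 samples
per carrier period is enforced everywhere.

Metrics follow the standard regulatory conventions:

* MI = PNP[MPa] / √(f_c[MHz]);
* I_SPPA = (1/T) ∫ p²/(ρc) dt over the burst, plane-wave impedance ρc
  (defaults ρ = 1000 kg/m³, c = 1480 m/s for water-tank numbers);
* I_SPTA = I_SPPA × duty cycle, reported in mW/cm².

The duty cycle may be passed explicitly: scanner-reported duty values do
not always equal cycles × PRF (multiplexed firing schemes report the duty
of the full sequence), so when reproducing tabulated settings the printed
duty is honoured as an input rather than recomputed.

For externally recorded waveforms the center frequency is defined as the
peak of the rectangular-windowed magnitude spectrum.

## Bubble dynamics

The radial model is a Rayleigh–Plesset equation for a gas bubble with a
thin elastic shell:

    ρ R R̈ = −(3/2) ρ Ṙ² + p_g (R₀/R)^{3γ} + p_v − p₀ − 2σ/R
             − 2χ (1/R₀ − 1/R) − δ_t ω ρ R Ṙ − p_ac(t)

* The ambient term −p₀ is included so that R = R₀ is a genuine rest state;
  the variant without it admits no equilibrium.  The initial gas pressure
  is closed by that equilibrium: p_g = p₀ + 2σ/R₀ − p_v.
* δ_t combines viscous (4μ/(ρωR₀²)) and re-radiation (ωR₀/c) damping.
  Thermal and shell-viscosity damping are **not** modelled.  ω is the
  angular center frequency of the driving pulse — a single scalar even for
  a broadband pulse.
* Shipped shell parameters: SonoVue χ = 0.22 N/m, γ = 1.0934 (SF₆),
  σ = 0.052 N/m; Sonazoid χ = 0.53, γ = 1.0699 (C₄F₁₀), σ = 0.042;
  Optison χ = 4.00, γ = 1.0731 (C₃F₈), σ = 0.9.  A gas-compressibility
  constant κ is stored with each agent for reference but enters no
  equation of this model.
* Medium defaults (mouse blood at 37 °C): ρ = 1057 kg/m³,
  μ = 5.996 mPa·s, c = 1570 m/s, p₀ = 101 325 Pa, p_v = 6267 Pa (water at
  37 °C).  p₀, p_v and c are declared assumptions and overridable.

Radiated pressure at distance r uses the incompressible near field,
p(r,t) = ρ (R²R̈ + 2RṘ²)/r, with R̈ evaluated from the model right-hand
side (never by numerically differencing the trajectory); the default
observation distance of 7 µm places the bubble mid-capillary.

**Numerics.**  The integrator is an adaptive Dormand–Prince 5(4) pair
specialised to the two-state ODE and JIT-compiled (numba), with relative
tolerance 1e-8, absolute tolerances 1e-12 m on R and 1e-6 m/s on Ṙ, and
the step capped at 1/32 of the carrier period so the output grid resolves
every cycle.  The driving pressure is linearly interpolated on its sample
grid (≥ 55 samples per period at the default 100 MHz rate).  A generic
scipy `solve_ivp` backend (RK45, LSODA fallback) integrates the identical
right-hand side and is used as an independent cross-check in the tests;
the two agree to < 0.01 percentage points on oscillation amplitude.  If R
falls below R₀/100 the integration halts and the trajectory is flagged
`collapsed` — flagged sweep points carry NaN metrics under a mask, never
fabricated values.  Oscillation amplitude is reported on the diameter
scale: absolute = D_max − D_min, percent = that divided by 2R₀.  Ties for
the sweep maximum resolve to the smallest R₀.

**Distribution weighting.**  A sweep metric m(R₀) is folded with a sized
population by mapping histogram bin centers d to R₀ = d/2, interpolating m
linearly onto them, multiplying by the count- or volume-normalized bin
weights and summing; a constant metric therefore has AUC equal to itself
under either normalization.  If more than 1% of the distribution mass
falls outside the sweep grid the call is rejected.

## Infusion pharmacokinetics

One-compartment constant-rate infusion with first-order elimination:
C(t) = (k₀/CL)(1 − e^{−k_e t})·C_bub with k_e = 0.6931/t_half and
CL = k_e·V_d.  Defaults: k₀ = 20 µL/min, V_d = 2.5 mL (mouse blood
volume), C_bub = 2.4 × 10⁸ particles/mL.  "Steady state" is defined as
99.8% of plateau (≈ 9 half-lives ≈ log₂ 500): with a 30 s half-life this
puts steady state at 4.5 min, consistent with the reference infusion
protocol; the fraction is configurable.  A helper converts perfusion-pump
settings to delivered flow for the 1 mL syringe geometry (× 0.058,
rounded to integer µL/min).

## Optical sizing

Per-particle equivalent diameter d_eq = 2√(area/π) and roundness
d_eq/d_max (capped at 1).  Particles below 0.7 µm are excluded (optical
resolution cutoff).  Histograms use left-closed 0.1 µm bins labelled by
center.  Count weighting is uniform; volume weighting ∝ d³.  Percentiles
(d10/d50/d90, polydispersity d90/d10) interpolate the weighted empirical
CDF with the midpoint convention — the estimator is not prescribed by any
convention we reproduce, so the simplest interpolating one is used.
Concentration = surviving count / imaging volume (6.2 × 10⁻⁶ mL default)
× dilution factor.  Fresh-vs-aged comparisons report percent changes plus
a Welch (unequal-variance) two-sample test on the diameters.
Cross-sectional-area matching scales a reference concentration by the
ratio of count-weighted mean squared diameters.

## Attenuation and cavitation spectra

Replicate recordings are reduced to rectangular-window periodograms and
arithmetically averaged per role.  No taper is applied by default (a Hann
option exists): the recordings are full pulse-echo records, not snippets
of stationary signals.  Attenuation = (baseline − sample) power in dB
divided by the acoustic path, default 8 cm (twice the 4 cm chamber,
out-and-back).  The bulk resonance is the in-band attenuation argmax, ties
to the lowest frequency.

Cavitation metrics per MI: subharmonic magnitude = **peak** dB excess over
the bubble-free background in 400–600 kHz (peak rather than band mean —
robust to band-edge leakage; configurable), and spectral integral =
trapezoidal integral of the *linear*-power excess over 0.2–10 MHz,
reported in dB (integrating dB values has no physical meaning).  The dB
reference (background spectrum) is recorded in the output metadata.

The threshold model is a four-parameter logistic
Y = d + (a−d)/(1+(x/c)^b) fitted by nonlinear least squares; the
inflection MI c is the cavitation threshold.  "Plateaus set to equal
values across datasets" is read as a **joint fit with shared a and d**
across agents (a = d would make the curve constant); the flag
`share_plateaus` exposes both readings.  95% CIs come from the parameter
covariance (t-based); fits whose c lands outside the data range are
flagged, and non-convergence raises with the best residual and start
point.  Regime boundaries are the MIs completing 5% and 95% of the a→d
transition, x_q = c·(q/(1−q))^{1/b}, giving the stable/transitional and
transitional/inertial splits; the geometric mean of the two bounds is c
for any slope.

## Response surfaces and the best-agent map

Calcein dose-response tables (agent, I_SPTA, concentration, % positive,
replicate) are reduced to replicate means on the measured factorial design
and interpolated with a separable spline, **both axes on log10**: the
measured concentrations span more than a decade and the intensities are
close to decade-spaced (3/50/358 mW/cm²), and low-order splines on a
linear intensity axis mis-recover realistic saturating surfaces by tens of
percentage points at cell midpoints, versus a few points on the log axis.
Spline order is capped at n_levels − 1 per axis, no smoothing (knot values
are reproduced exactly), output clipped to [0, 100], extrapolation
rejected.  The best-agent map takes the per-cell argmax with the winning
margin (best minus second best); exact ties are listed rather than broken
by agent order.

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes; all randomness flows from `numpy.random.default_rng(seed)` and
identical arguments give bit-identical output.

* **Populations** — lognormal diameters (strictly positive, parameterised
  by median and d90/d10 via σ_ln = ln(psd)/2.5631), areas back-computed,
  max diameter from a truncated-normal roundness draw (0.94 ± 0.02).  The
  shipped per-agent scenarios use the published count-normalized medians
  and polydispersities (SonoVue 1.7 µm / 2.46, Sonazoid 1.9 µm / 2.06,
  Optison 3.3 µm / 2.15).
* **Waveform sets** — a deterministic broadband click designed in the
  frequency domain (strictly positive, null-free spectrum to ~12 MHz);
  the sample replicates are the baseline filtered so the spectral power
  deficit equals profile × path; optional additive white noise at a stated
  dB level below the peak.
* **MI responses** — 4PL evaluations plus Gaussian dB noise per replicate.
* **Dose-response surfaces** — Hill saturation in concentration with an
  EC50 that falls with intensity as a power law, Gaussian noise in
  percentage points, clipped to [0, 100].

What the generators do **not** emulate: scattering physics of real echoes
(the attenuation imprint is exact by construction), hydrophone/receiver
transfer functions, bubble destruction at high MI (responses above
MI ≈ 1.2 in real measurements roll off due to nearfield destruction and
are excluded from fitting by configuration), bubble–bubble interaction,
and non-lognormal size tails.  Passing round-trip tests therefore shows
the analysis chain is self-consistent and correctly inverts its stated
data model — not that the data model captures every feature of laboratory
recordings.

## Problem sizes

The default study pipeline synthesizes a 1.8 MHz / 20 µs / 0.268 MPa
treatment burst, sweeps 194 equilibrium radii (0.35–10 µm, 50 nm steps)
per agent, weights by 20 000-particle synthetic populations, and runs in
a few seconds on one core thanks to the compiled integrator.  The CI
coverage study uses 200 seeded repeats of 90-point 4PL fits per threshold
value.

## Known limitations

* With the default damping (viscous + re-radiation only) the simulated
  treatment-pulse oscillation maxima reach ≈ 174/179/143% of the
  equilibrium diameter for SonoVue/Sonazoid/Optison.  This is a direct
  consequence of the damping model: the linearised steady-state response
  at resonance, x = p_A/(ρR₀²ω₀²δ_t), already predicts a ~160% diameter
  excursion for SonoVue at 0.268 MPa with δ_t ≈ 0.52.  Published
  simulations of comparable exposures that additionally include thermal
  and shell-viscosity losses (total δ_t of order 2) give maxima several
  times smaller; the *relative ordering* of the agents
  (Sonazoid ≥ SonoVue ≫ Optison at the sweep maximum, SonoVue first after
  distribution weighting) is insensitive to this choice, the absolute
  amplitudes are not.  The values are robust to solver tolerance
  (1e-3…1e-8 agree to three digits) and to the integrator backend.
* The 4PL CIs are fit-parameter (covariance) intervals, not
  across-experiment intervals; with few replicates the two can differ.
* Amplitudes under short broadband imaging pulses depend on the exact
  recorded waveform, which a synthesized tone burst cannot stand in for;
  only the long treatment burst is synthesized from stated parameters.
* The RP model assumes spherical oscillations, a static unbounded liquid,
  and no buckling/rupture shell regimes; collapse is flagged, not
  modelled.
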