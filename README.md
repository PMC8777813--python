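# sonobubble

Microbubble acoustics for **low-intensity sonoporation** — the use of
ultrasound-driven contrast-agent microbubbles (SonoVue, Sonazoid, Optison)
to transiently permeabilize cell membranes and enhance drug delivery, e.g.
in pancreatic cancer therapy.  The package is aimed at therapeutic-ultrasound
and contrast-agent researchers who need the full desk-scale computational
chain between "scanner settings" and "which bubble works best":

* **pulses** — tone-burst synthesis and acoustic output metrics
  (PNP/PPP, MI, I_SPPA, I_SPTA, duty cycle);
* **bubble dynamics** — a shell-model Rayleigh–Plesset equation integrated
  over equilibrium-radius sweeps, with radiated-pressure metrics and
  size-distribution weighting;
* **pharmacokinetics** — constant-rate-infusion bubble concentration;
* **sizing** — optical particle tables → dual-normalized histograms,
  d10/d50/d90, polydispersity, concentration, in-vial stability;
* **spectra** — attenuation spectroscopy (bulk resonance) and cavitation
  thresholds via a four-parameter logistic fit;
* **mapping** — interpolated dose-response surfaces and the per-condition
  "best agent" map;
* **synthetic** — seeded generators so the whole pipeline is testable
  without laboratory data.

## The models

A bubble of equilibrium radius R₀ with shell stiffness χ, interfacial
tension σ and polytropic gas exponent γ in a liquid of density ρ obeys

ρ R R̈ = −(3/2) ρ Ṙ² + p_g (R₀/R)^{3γ} + p_v − p₀ − 2σ/R − 2χ(1/R₀ − 1/R) − δ_t ω ρ R Ṙ − p_ac(t),

with p_g = p₀ + 2σ/R₀ − p_v and damping δ_t = 4μ/(ρωR₀²) + ωR₀/c
(viscous + re-radiation).  The circulating concentration during an
infusion at rate k₀ into a blood volume V_d is
C(t) = (k₀/CL)(1 − e^{−k_e t})·C_bub, k_e = 0.6931/t_½, CL = k_e V_d.
Cavitation thresholds come from the four-parameter logistic
Y = d + (a−d)/(1+(x/c)^b) fitted to subharmonic or broadband spectral
metrics versus mechanical index; the inflection c is the threshold.
See `docs/methods.md` for conventions, numerics and limitations.

## Worked example

```python
import numpy as np
from sonobubble import (synthesize_tone_burst, pulse_metrics, AGENTS,
                        MOUSE_BLOOD, BubbleModel, InfusionModel,
                        gen_mi_response, fit_4pl)

# the in vivo treatment exposure, synthesized from its stated parameters
pulse = synthesize_tone_burst(1.8e6, 20e-6, 0.268e6, label="treatment")
m = pulse_metrics(pulse, duty_cycle=0.011)
print(f"MI = {m.mi:.2f}, I_SPPA = {m.i_sppa:.2f} W/cm2, I_SPTA = {m.i_spta:.0f} mW/cm2")

# sweep 194 equilibrium radii for SonoVue and find the largest response
sweep = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, pulse).sweep()
r0, pct = sweep.max_osc_pct()
print(f"SonoVue: max oscillation {pct:.1f}% of D0 at R0 = {r0*1e6:.2f} um")

# how concentrated do infused bubbles get in a mouse?
pk = InfusionModel.from_ul_per_min(20.0, 2.5, 30.0, 2.4e8)
print(f"plateau = {pk.plateau:.2e} ppmL, steady state at "
      f"{pk.time_to_fraction()/60:.1f} min")

# joint cavitation-threshold fit on synthetic sweeps (1 dB noise)
mi = np.linspace(0.01, 1.2, 26)
resp = {name: gen_mi_response(0.0, -30.0, 8.0, c, mi, 1.0, 3, seed=i, label=name)
        for i, (name, c) in enumerate([("SonoVue", 0.44), ("Sonazoid", 0.21),
                                       ("Optison", 0.39)])}
print(fit_4pl(resp, share_plateaus=True).summary())
```

prints

```
MI = 0.20, I_SPPA = 2.05 W/cm2, I_SPTA = 23 mW/cm2
SonoVue: max oscillation 173.9% of D0 at R0 = 2.10 um
plateau = 1.39e+06 ppmL, steady state at 4.5 min
4PL cavitation-threshold fit (plateaus shared; residual RMS 0.935 dB, dof 226)
agent              a        d       b   c (MI)             95% CI(c)               regimes
SonoVue         0.01   -29.98    7.97    0.438   (0.433, 0.443)   (0.303, 0.633)
Sonazoid        0.01   -29.98    8.41    0.212   (0.209, 0.215)   (0.149, 0.301)
Optison         0.01   -29.98    8.31    0.392   (0.387, 0.396)   (0.275, 0.558)
```

The MI of 0.20 is the regulatory index of the treatment pulse; the sweep
maximum says which bubble size responds most strongly to it (here a
2.1 µm-radius SonoVue bubble, oscillating at 174% of its resting
diameter under viscous + re-radiation damping — see the limitations
section of `docs/methods.md` for why fuller damping models give smaller
amplitudes).  The infusion plateau and 4.5 min settling time set the
bubble dose seen by a tumor, and the fitted `c` column recovers each
agent's cavitation-threshold MI with its confidence interval and the
stable/transitional/inertial regime boundaries.

A command-line surface wraps the same functions
(`sonobubble pulse synth …`, `sonobubble bubble sweep …`,
`sonobubble pk steady …`, `sonobubble study-run`); every pipeline run
writes its resolved configuration next to its outputs and is
byte-reproducible from it.

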