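# quenchkit

Inner-filter-effect-aware analysis of fluorescence quenching titrations.

## The problem

Fluorescence titrations are a standard route to host–guest association
constants: a fluorescent receptor (often 10–20 μM) is titrated with a
quencher, and the Stern–Volmer slope of F₀/F against quencher concentration
is read as the association constant K of a 1:1 complex. Many common
quenchers — nitroaromatic explosives (TNT, picric acid, nitrobenzene, …)
being the canonical example in chemosensing — absorb strongly at the
excitation wavelength. Part of the excitation beam is then absorbed before
it reaches the volume the detector samples, and the intensity drops even
when no complex forms at all. This **excitation inner filter effect (IFE)**
mimics quenching: ignore it and you report binding where there is none, or
overestimate a genuine constant several-fold.

`quenchkit` is for spectroscopists and supramolecular chemists who want this
artifact screened, corrected and documented as part of every titration
analysis, with the corrected and uncorrected constants (and their ratio)
always on record.

## The model

For emission collected from the centre of a 1 cm cell the correction
follows from Beer's law:

    F_corr = F · 10^(ΔA·d_eff),   ΔA = A − A₀  (at λ_ex, 1 cm basis)

with d_eff = 0.5 cm by default, i.e. the familiar F_corr = 10^(ΔA/2)·F.
The geometry is parameterised because the factor depends on the emitting
volume the detector samples.

Downstream of the correction:

- **1:1 speciation**: [HG] is the physically admissible root of
  K·x² − (K(Hₜ+Gₜ)+1)·x + K·Hₜ·Gₜ = 0, evaluated in cancellation-free form.
- **Stern–Volmer**: F₀/F = 1 + K[Q] fitted with the intercept fixed at 1
  (free intercept available as a diagnostic), with an F-test curvature flag —
  upward curvature at high [Q] is the signature of an uncorrected IFE.
- **Global absorbance fit**: A(λ,i) = ε_H(λ)[H]ᵢ + ε_G(λ)[G]ᵢ + ε_HG(λ)[HG]ᵢ
  over all wavelengths and titration points at once, with an
  identifiability flag when complexation leaves the spectra unchanged.
- **TCSPC lifetimes**: reconvolution fits of 1–3 exponentials with Poisson
  weighting; static quenching leaves lifetimes invariant, dynamic quenching
  shortens them as τ₀/τ = 1 + k_q·τ₀·[Q].
- **Sequential diagnosis**: screen IFE → correct → compare corrected and
  uncorrected Stern–Volmer fits → consult lifetimes → verdict
  (`no_quenching_ife_artifact`, `static_quenching`, `dynamic_quenching`,
  or `mixed_or_inconclusive`).

A synthetic-data module generates titrations and decays with known ground
truth (including the IFE attenuation the correction removes), so every
estimator is validated by parameter recovery.

## Worked example

A simulated 10 μM receptor titrated cell-by-cell with an absorbing quencher
(ΔA up to 0.30 AU at λ_ex) that also genuinely binds (K = 3000 M⁻¹,
non-emissive 1:1 complex, 1% intensity noise):

```python
import numpy as np
from quenchkit import (SimulationScenario, simulate_fluorescence_titration,
                       run_quenching_workflow, format_report)

scenario = SimulationScenario(
    K_true=3000.0,            # ground-truth association constant, M^-1
    host_total=10e-6,         # 10 uM receptor, cell-by-cell titration
    guest_grid=tuple(np.linspace(0.0, 300e-6, 13)),
    eps_guest=1000.0,         # quencher absorbs at the excitation wavelength
    seed=7,
)
series = simulate_fluorescence_titration(scenario)
report = run_quenching_workflow({"titration": series})
print(format_report(report))
```

prints

```
Quenching diagnosis report
==========================
Inner filter screening: correct_required
  max ΔA(λex) = 0.2999 AU
  max ΔA(λem) = not assessed
  max correction factor = 1.412
Stern-Volmer fits (F0/F = 1 + K[Q]):
  uncorrected: K = 5272 ± 3.4e+02 M^-1 [curved]
  corrected:   K = 3010 ± 67 M^-1
  overestimation ratio (uncorrected/corrected): 1.75
Lifetime evidence: not_measured
Association class (corrected K): stable
FINAL VERDICT: static_quenching
```

The uncorrected fit overestimates the association constant by 75% (and its
plot is significantly curved); the corrected fit recovers the ground truth
within its quoted uncertainty. With decay histograms supplied in the
config, the lifetime invariance test replaces the low-concentration caveat.

The same pipeline is available from the shell:

```sh
quenchkit simulate --config scenario.yaml --out titration.csv
quenchkit correct  --input titration.csv --output corrected.csv
quenchkit sv-fit   --input titration.csv
quenchkit workflow --config workflow.yaml --out report.yaml
```

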