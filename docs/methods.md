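# Methods

## Scope and model

`quenchkit` analyses fluorescence quenching titrations of a fluorescent
host H by a quencher/guest G under the 1:1 mass-action model
H + G ⇌ HG, K = [HG]/([H][G]), with explicit treatment of the excitation
inner filter effect (IFE). The intended regime is the cell-by-cell
titration design: constant host (order 10 μM), guest added up to tens of
equivalents (≲ 300 μM), absorbance and fluorescence read per cell.

### Speciation

[HG] is the smaller root of K·x² − (K(Hₜ+Gₜ)+1)·x + K·Hₜ·Gₜ = 0, computed
as 2c/(−b+√(b²−4ac)) to avoid cancellation. Mass balance holds to ~1e−12
relative across K ∈ [0, 1e8] M⁻¹ and totals down to 1e−8 M; the K = 0 and
K → ∞ limits are exact. The test suite checks the solver against an
independent bisection of the mass-balance residual.

### Inner filter correction

F_corr = F·10^(ΔA_ex·d_ex), with ΔA_ex the absorbance change at λ_ex on a
1 cm basis relative to the mandatory zero-guest reference point, and
d_ex the effective excitation path in cm. The default d_ex = 0.5 cm
(centre-of-cell detection in a 1 cm cuvette) gives the classical
10^(ΔA/2) factor. d_ex is a parameter, not a constant, because the factor
depends on the emitting volume the detector actually samples; users should
verify it for their instrument. The symmetric emission-side factor
10^(ΔA_em·d_em) is implemented but off by default: the excitation side is
the dominant artifact in the target experiments. Negative ΔA is accepted
(factor < 1) with a logged warning.

Screening thresholds: max ΔA_ex < 0.01 AU → negligible; > 1.0 AU →
redesign suggested (the correction factor exceeds ~3, and a different
excitation wavelength or a shorter-path cell is preferable to correcting);
otherwise correction required. These two constants are policy defaults of
this package, configurable per run and echoed into every report.

### Stern–Volmer analysis

F₀/F = 1 + K·[Q] is fitted by least squares with the intercept fixed at 1
(the ratio at zero quencher is 1 by construction); a free intercept is
available and its deviation from 1 reported as a systematic-error
diagnostic. The x-axis is the added (total) guest concentration by
default — appropriate when host ≪ guest — with an iterated free-guest
refinement (re-solving speciation at the current K until convergence) as
an option; on synthetic data the refinement removes the ~2% depletion bias
of the total-concentration axis. Points are never silently truncated: a
`max_points` option exists and logs.

Curvature: an F-test (α = 0.05, single test per series, no multiplicity
correction) compares the linear model against one with an added quadratic
term. Uncorrected IFE produces upward curvature at high [Q]; the flag is
carried on every fit.

**Uncertainty of K.** Every ratio F₀/F shares the single measured F₀, so
ratio errors are positively correlated and part of the relative error of
F₀ aliases into the slope. The reported stderr therefore adds, on top of
the ordinary least-squares term σ²/Σq², a shared-reference term
σ_rel²·(Σqᵢrᵢ/Σq²)² with σ_rel estimated from the residual scatter. On
replicate synthetic titrations the empirical spread of K matches this
estimate, whereas the plain OLS stderr underestimates it roughly
three-fold in the simulated design.

Static quenching is modelled with a non-emissive 1:1 complex (the standard
Stern–Volmer interpretation); an emissive-complex fraction is a simulator
option but not a fit parameter.

### Global absorbance fit

Multi-wavelength absorbance titrations are fitted to
A(λ,i) = ε_H(λ)[H]ᵢ + ε_G(λ)[G]ᵢ + ε_HG(λ)[HG]ᵢ with known pure-component
ε_H, ε_G. The problem is separable: for fixed K the non-negative ε_HG(λ)
is a clipped per-wavelength linear solve, so the outer problem is a
bounded 1-D minimisation over log₁₀K (bounds 10⁻⁴–10⁸ M⁻¹; the log
parameterisation conditions the search and enforces K ≥ 0). The stderr
comes from the numerical curvature of the residual sum of squares at the
optimum. The fit is flagged non-identifiable when the best-fit binding
signal max|A_pred(K̂) − A_pred(0)| is below 3× the residual noise — e.g.
when ε_HG ≈ ε_H + ε_G, in which case complexation is spectrally silent and
no absorbance-derived K is meaningful.

### Association-strength classification

K < 1 M⁻¹, or K not significantly above zero (K < 2·stderr) →
*statistical* (complexes present only at random-proximity level);
K ≥ 100 M⁻¹ and significant → *stable*; otherwise *weak*. The two bounds
are package policy, configurable.

### TCSPC decay analysis

Decays are fitted as Σaᵢ·exp(−t/τᵢ) (1–3 components) reconvolved with the
instrument response (measured histogram, Gaussian, or delta), minimising
the Poisson-weighted χ² with variance max(counts, 1) — standard TCSPC
practice that avoids zero-variance channels. Amplitudes are solved by
non-negative linear least squares at each trial lifetime set (variable
projection) and the lifetimes optimised over log τ, bounded to
[channel width, 10× record length], from five log-spaced starts (closely
spaced lifetimes trap local minima). The fit window starts at the IRF (or
decay) peak channel by default. Parameter covariance is Gauss–Newton
(JᵀWJ)⁻¹ over amplitudes and lifetimes. Warnings are raised when
lifetimes collapse within 1% or a component's amplitude falls below 2% of
the total; model order is chosen by the analyst, with a nested F-test
helper (α = 0.05) available rather than automatic selection. The IRF shift
parameter defaults to 0 and stays frozen unless a measured IRF is used.

Average lifetimes: ⟨τ⟩_amp = Σaᵢτᵢ/Σaᵢ and ⟨τ⟩_int = Σaᵢτᵢ²/Σaᵢτᵢ, with
⟨τ⟩_int ≥ ⟨τ⟩_amp (Cauchy–Schwarz; the single-component case returns τ
exactly for both).

**Static/dynamic discrimination.** A decay series across quencher levels
(zero reference mandatory) is *invariant* when every lifetime and
amplitude fraction lies within k standard errors (default k = 3, with a
small relative floor) of the reference fit; *dynamic* when τ₀/τ − 1
regressed through the origin on [Q] has a significantly positive slope
(one-sided t-test, α = 0.05), the slope being k_q·τ₀; otherwise
*inconclusive*. Invariant lifetimes with decreasing corrected intensities
mean static quenching: the complexed fluorophores are dark, the surviving
ones decay unchanged.

## The sequential workflow

Order of evidence: screen IFE → correct → fit both Stern–Volmer forms →
consult lifetimes → verdict. Decision rules:

1. corrected intensities flat while uncorrected decrease →
   `no_quenching_ife_artifact`;
2. corrected quenching detected and lifetimes invariant →
   `static_quenching` (corrected K is the association constant). With no
   decay data, dynamic quenching is discounted — with a mandatory logged
   caveat — when the maximum quencher concentration is below 1 mM, too low
   for diffusion-limited collisional quenching to be observable on ns
   lifetimes;
3. lifetimes dynamic and the corrected steady-state K matching the
   lifetime slope within 25% relative → `dynamic_quenching`;
4. otherwise `mixed_or_inconclusive`.

"Detected" means K > 4·stderr (with the shared-reference-aware stderr).
The 4σ policy, stricter than a casual 2σ, keeps the false-quenching rate
per unattended run near 1e−5 while any complex in the stable range clears
it by an order of magnitude; it is configurable (`detection_z`). The
redesign branches (change λ_ex, use a short-path cell) are emitted as
textual recommendations, never automated. Reports echo every threshold
used and are deterministic given the inputs.

## Synthetic data: what it emulates and what it does not

The generators reproduce the study conditions the estimators are meant
for: constant host 10 μM (configurable 10–20 μM), guest grids to 300 μM,
1:1 static quenching with a non-emissive complex, guest absorbance at λ_ex
(so ΔA_ex = ε_G·[G]ₜ, up to 0.30 AU at ε_G = 1000 M⁻¹cm⁻¹ — chosen to give
a ~1.4× correction factor, comfortably inside the "correct, don't
redesign" band), and the *applied* attenuation 10^(−ΔA_ex·d_ex) that the
correction removes. Noise is multiplicative Gaussian on F (1% default) and
additive Gaussian on A (0.2% of the value), typical photometric precision.
TCSPC decays carry true Poisson counting noise on the reconvolved
expectation. Everything is deterministic given the scenario seed;
replicates use seed + index.

Not emulated: wavelength-dependent detector response, scattering,
reabsorption of emitted photons, emission-wavelength IFE (unless enabled),
cumulative-dilution titration errors, IRF colour shift and afterpulsing,
and diffusion physics for dynamic quenching (dynamic test cases shorten τ
directly via τ₀/(1 + k_q·τ₀[Q])). Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to instrument pathologies.

Decay problem sizes in the tests (512–1024 channels, records of ~5–6
lifetimes, peak 10⁴ counts) keep the dimmest fitted channels above ~50
expected counts, where the Gaussian approximation behind the
Poisson-weighted χ² is accurate and reduced χ² centres on 1; longer
records would need true Poisson-likelihood fitting.

The canonical workflow scenarios exercised in the tests use
single-exponential decays and set the invariance multiplier to 5 (rather
than the default 3): three lifetime comparisons per run are a family of
tests, and an automated verdict should not flip on one 3σ fluctuation of
an unquenched lifetime; dynamic quenching moves lifetimes by far more
than 5σ, so discrimination power is unaffected.

## Numerical choices and degenerate inputs

- Concentrations are mol/L internally; readers convert from declared units.
- Absorbances are stored on a 1 cm basis; geometry enters only at
  correction time.
- The zero-guest reference point is mandatory (F₀ and A₀ are defined
  against it), never inferred from the minimum titrant.
- Flat intensity data give K = 0 with r² reported as NaN (no variance to
  explain).
- Equal spectra for complex and free species give `identifiable = False`,
  not an arbitrary K.
- The equilibrium solver clips [HG] to min(Hₜ, Gₜ) to guard rounding in
  the strong-binding limit.
- Delimiters are auto-detected among comma/tab/semicolon; decimal points
  only.

## Known limitations

- Only 1:1 stoichiometry; no 1:2/2:1 models, Job plots, or global
  multi-wavelength fluorescence fitting.
- The Stern–Volmer route assumes a non-emissive complex; a partially
  emissive complex biases K low.
- The IFE correction is a point-geometry approximation; strongly absorbing
  samples (ΔA ≳ 1) should be redesigned, not corrected.
- Lifetime fitting is per-decay; no global (linked-lifetime) analysis
  across quencher levels.
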