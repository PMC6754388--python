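# Methods

## The model

The mat is treated as a one-dimensional porous slab in contact with the
atmosphere at its upper surface. Porewater O₂ concentration C(z, t) obeys

    ∂C/∂t = P(z) − R(C) + D′ ∂²C/∂z²

with depth z positive downward from the mat–atmosphere interface.
Photosynthesis is light-limited Michaelis–Menten,
P = PAR(z)·V_max,prod/(K_m,prod + PAR(z)), with PAR attenuating
geometrically, PAR(z) = PAR₀ (1 − f)^(z/δ); aerobic respiration is
O₂-limited, R = C·V_max,resp/(K_m,resp + C). The equation is integrated by
the explicit forward-time centred-space (FTCS) scheme on a uniform grid.
Diffusion acts on porewater concentration directly, so porosity φ cancels
inside the slab; φ enters only the areal quantities — interface fluxes
(J = −φD′ ∂C/∂z, Fick's first law with tortuosity-corrected diffusivity)
and depth integrals of volumetric rates.

Assumptions worth stating plainly: the geometry is 1D (no lateral
heterogeneity), kinetic parameters are depth-independent, temperature is
constant, there is no internal CH₄ or sulphur redox cycling coupled to the
O₂ field, and the light field is a single scalar PAR (no spectral
resolution). Growth and death of the community are not modelled; the
kinetics describe a mat in its present state.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| V_max,prod | 2.1 | nmol L⁻¹ s⁻¹ | maximal volumetric O₂ production |
| K_m,prod | 1000 | µE m⁻² s⁻¹ | light half-saturation |
| V_max,resp | 1.75 | nmol L⁻¹ s⁻¹ | maximal volumetric respiration |
| K_m,resp | 250 | nmol L⁻¹ | O₂ half-saturation |
| PAR₀ | 1500 | µE m⁻² s⁻¹ | surface irradiance |
| f / δ | 0.01 / 0.071 mm | — | fractional PAR loss per depth step |
| φ | 0.97 | — | porosity |
| D′ | 1 × 10⁻⁵ | cm² s⁻¹ | tortuosity-corrected diffusivity |
| Δx | 0.071 | mm | grid spacing (microsensor resolution) |
| domain depth | 20 | mm | configurable; matches the sampled sections |
| top boundary | 230 | µmol L⁻¹ | air-equilibrated O₂, warm fresh water |
| bottom boundary | no-flux | — | optional fixed concentration |

The oxic-day top boundary (230 µM) and the domain depth are design choices,
not measured constants; every test that depends on them is a property
(conservation, ordering, recovery), not a point value. Note that the
default kinetic maxima integrate to areal rates of order 1 mmol m⁻² d⁻¹
over any plausible domain — with these constants the model describes the
shape of microprofiles and the relative response to boundary changes, not
field-scale areal production, which enters the balance and extrapolation
modules as measured areal inputs instead.

## Numerical choices

* **Stability.** FTCS requires D′Δt/Δx² < 0.5; the solver raises a
  configuration error naming the offending number otherwise. The native
  grid (Δx = 0.071 mm, Δt = 1 s) gives 0.198. In practice we keep the
  number ≤ ~0.25: with clipping and Michaelis–Menten respiration active
  near the anoxic floor, marginally stable steps (~0.4) can enter a small
  limit cycle and never meet a tight residual tolerance.
* **Steady state.** Two modes: a fixed 1200 × 1 s run reproducing the
  original fixed-iteration procedure, and a converge mode (default)
  iterating until max |ΔC/Δt| < 10⁻⁴ nM s⁻¹ (tolerance configurable, max
  10⁶ steps, explicit non-converged flag). The fixed 1200 s run is short
  relative to the diffusion time over 20 mm (L²/D′ ≈ 4 × 10⁵ s), so
  converge mode is used wherever a true steady state matters.
* **Conservation.** The reported top efflux adds a half-cell reaction
  correction φ(Δx/2)(P₀ − R₀) to the two-point Fick term; with that
  convention the sum of outward interface fluxes equals the trapezoidal
  depth integral of φ(P − R) essentially exactly at discrete steady state
  (the conservation tests require 0.5%).
* **Negativity.** Respiration at a node is capped at C/Δt, and any negative
  concentration after an update is clipped to zero with a logged warning.
* **Curvature inversion.** Net rates from measured profiles use centred
  second differences (non-uniform-grid safe); the two edge nodes take the
  curvature of the cubic through their nearest four points. Double
  differentiation amplifies sensor noise roughly as σ/Δx², so noisy
  profiles should be smoothed (optional 3-point moving average) before
  inversion; inversion of near-balanced profiles (production ≈ respiration)
  has a poor relative error even noiseless, because the integral being
  recovered is a small difference of large terms.
* **Calibration.** (V_max,prod, V_max,resp) are fitted by bounded
  least squares against profiles resampled onto the model grid, with each
  forward run warm-started from the previous steady state. Two pitfalls are
  handled: the converge tolerance during fitting must leave far less
  steady-state drift than the finite-difference step moves the profile
  (defaults: 10⁻⁵ nM s⁻¹ and 5% steps), and a single daytime profile leaves
  the two maxima nearly collinear wherever O₂ saturates respiration — the
  optional joint fit against a paired night (PAR = 0) profile resolves
  this, mirroring how paired day/night microprofiles are used in practice.
* **Units.** Internal solver arithmetic and unit conversions are exact
  rational factors centralised in one module (mm/µM/nM s⁻¹/mmol m⁻² d⁻¹ at
  the interfaces, SI inside); round trips are tested to 12 digits.
  Report-time rounding to printed precision (2 significant figures,
  half away from zero) is the only lossy step and is confined to the
  reporting layer.

## Flux balance and extrapolation arithmetic

Organic-matter accretion integrates wt%C(z)/100 · (1 − φ) · ρ_particle over
the mat thickness (trapezoids, constant extension below the deepest sample)
and divides by the accretion age (6 cm, 9 yr, ρ = 2.65 g cm⁻³ by default;
year = 365 d, C = 12.011 g mol⁻¹). The dark-incubation CH₄ rate is halved
by default to account for oxic-day inhibition of methanogenesis. The
O₂-equivalent ledger normalises to 4-electron transfers — CH₂O → CO₂ and
O₂ → 2H₂O are each 4 e⁻, CH₄ → CO₂ is 8 e⁻ — fixing the conversion factors
at {O₂: 1, C_org: 1, CH₄: 2}; they are immutable constants.

Global scaling is exact linear arithmetic on user-stated scenarios (land
area, coverage fraction, areal rate); the Earth surface area constant is
5.10 × 10⁸ km². The package asserts nothing about actual Archean land area
or climate — reference fluxes for comparisons are config inputs with
citations expected from the user.

## Synthetic data: what it does and does not show

The generators emulate the measurements the pipeline consumes: O₂
microprofiles are forward-model steady states plus additive homoscedastic
Gaussian sensor noise (σ default 2 µM); diel series override surface PAR
per time point; wt%C declines exponentially between the observed anchors
(12 wt% at surface, 1 wt% at depth, 5 mm decay depth); cell counts are
log-uniform in 10⁸–10⁹ cells cm⁻³, sorted non-increasing with depth. Every
artifact embeds its generating parameters, so calibration and inversion are
tested closed-loop against known truth.

Passing those tests shows the chain is self-consistent: it recovers
parameters and rates from data its own model generated. It does not show
that the model describes a real mat — real microprofiles carry
heteroscedastic sensor noise, diffusive boundary layers above the surface,
depth-varying porosity and kinetics, and diel hysteresis, none of which the
generators produce.

## Scaled problem sizes

Library defaults keep the microsensor-resolution grid (0.071 mm, 1 s).
Tests and the packaged pipeline configuration use coarser, faster
discretisations chosen to keep discretisation error well inside the bands
they assert: 10–30 mm domains at 0.142–0.5 mm spacing with 8–60 s steps
(stability number ≤ 0.25 throughout), 20 replicates for the calibration
recovery experiment, and 1000 noise realisations for the noise-sd contract.

## Known limitations

* The explicit scheme makes converge-mode runs O(L²/D′Δt) steps; implicit
  or direct steady-state solvers would be faster but are deliberately out
  of scope to keep one discretisation everywhere.
* Two-point interface gradients under-resolve the flux by the half-cell
  reaction term at coarse spacing; the simulator corrects for it, plain
  Fick estimates on measured profiles do not.
* The sensitivity scan perturbs one parameter at a time; no interaction or
  variance-based analysis.
* Calibration fits exactly two parameters; the half-saturation constants
  and light attenuation are taken as known.
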