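# Methods

## Scope and geometry

The package simulates penetration of a hydrophilic ionic active ingredient
(AI) from evaporating sessile droplets across an isolated, astomatous plant
cuticle into a stirred receiver bath. The cuticle is reduced to a 1-D slab
x ∈ [0, b] (x = 0 under the droplet, x = b at the bath); all heterogeneity
perpendicular to the thickness is absorbed into an areal porosity and a
tortuosity exponent. The droplet is a spherical cap; its spreading phase and
the brief third evaporation stage are outside the model, so integration
starts from the post-spreading state (measured initial contact area at the
nominal 1 µL volume) at t = 0.

## Transport in the cuticle

Both species diffuse down gradients of the pore-volume-weighted
concentration w_i = ε c_i:

  ∂w_AI/∂t = ∂/∂x (D_AI ∂w_AI/∂x)
  ∂w_w/∂t  = ∂/∂x (D_w ∂w_w/∂x) − (2/r_p)(1−ε) ∂Γ/∂t

with the auxiliary chain evaluated pointwise from the local water
concentration: Langmuir monolayer Γ(c_w) = Γ_S β c_w/(1+β c_w); pore radius
r_p(Γ) = r_w[1 + 1/sin(1/(Γ r_w² N_A))] (a monolayer-geometry relation,
inverse of Γ(r_p)); porosity ε = (n₀+1) π r_p²/L²; effective diffusivities
D_i = D_i^bulk ε^{F_s/(2−F_s)}. The printed source form of the porosity
relation is dimensionally inconsistent; the areal-pore-fraction reading used
here matches its verbal description (evenly distributed circular pores,
n₀ = η_pore L² of them per L²) and gives ε ≈ 0.031 at the maximum radius.
The tortuosity exponent degenerates to the classical ε-scaling at F_s → 1.

Boundary conditions: c_AI(b) = 0 and c_w(b) = c_w^pure (stirred bath);
c_w(0) = (1 − v̄_AI c_AI(0))/v̄_w (volume conservation in the drop, clamped
at zero); c_AI(0) equals the drop concentration, which obeys its own ODE.

Initial state: no AI in the pores; pure water; pores at γ·r_p_max with
γ = 0.97. Two constants are *derived* rather than taken at their printed
values, so that the initialization is exactly self-consistent:

- Γ_S from the r_p(Γ) relation at r_p_max (9.683e-4 mol/m², matching the
  printed value to 4 significant figures);
- the Langmuir parameter β from the identity Γ(c_w^pure; β) = Γ(γ·r_p_max)
  (β = 5.40e-4 m³/mol). The printed β = 3.77e-5 m³/mol corresponds to
  γ ≈ 0.70 and, when used directly, collapses the initial porosity and
  contradicts every reported simulation observable; it remains available as
  an explicit override (`beta_H2O`).

## Droplet evaporation and hygroscopic growth

Evaporation follows the Popov quasi-steady vapor-diffusion kernel with
Λ = D_evap ψ/ρ_w and ψ = M_w P_v(1−H)/(RT). The shape integral f(θ) is
evaluated by adaptive quadrature of a decaying-exponential form (analytic
limits f(0⁺) = 4/π, f(π/2) = 2 are verified to 1e−6) and tabulated on a
0.1° grid with cubic interpolation for use inside right-hand sides; the
quadrature truncation keeps the neglected tail below 1e−12. The kernel is
validated in the literature up to 150°; larger angles are permitted with a
warning.

Stage sequence: constant contact radius (CCR) from θ₀ down to
θ_rec = θ₀(1 − 0.1264), then constant contact angle (CCA). The receding time
is located by event detection and cross-checked against the closed-form
contact-angle quadrature (agreement to 0.1 %). CCR carries no hygroscopic
correction, exactly as the stage equations are stated in the source model.

Above the point of deliquescence (H + ξ > POD_AI) the CCA rate is the Popov
rate multiplied by the logistic deliquescence factor
χ̄ (V/V₀)(V/V_Del − 1), with χ̄ = χ c₀² (c₀ in g/L), and by the solubility
cap (1 − c/c_POD); plus a small water back-flux term from the cuticle.
V_Del = m_∞(Φ) M_w,AI c V/ρ_w depends on the state only through the drop's
AI content, so it tracks the AI as it is lost to binding and diffusion; the
division V/V_Del is guarded by a 1e−18 m³ floor so the AI-free limit is
plain evaporation. Below the POD (or with hygroscopic growth switched off)
the bare Popov CCA rate applies.

The empirical CaCl₂ equilibrium curves — final solution weight percent
c_mass%(Φ) and water uptake m_∞(Φ), both two-exponential fits valid on
Φ ∈ [0, 0.97] — are hard-coded for CaCl₂ but sit behind a
`HygroscopicMaterial` interface (POD + two coefficient quadruples) so
another salt/adjuvant combination can supply its own triple. The adjuvant
shifts both the POD and the humidity argument by the same ξ (an assumed
one-to-one correspondence); ξ = 5 %RH is itself an assumption of the source
calibration and stays a free parameter.

## Drop AI balance and ion binding

d(Vc)/dt = −k c + η_pore A_drop A_Π [D_AI ∂(εc_AI)/∂x]|₀. Binding is
irreversible and surface-only; bound moles accumulate in the ledger. The
control-volume area A_Π is never given a numeric value in the source; the
default A_Π = L²/(n₀+1) ≈ 1/η_pore is the unique choice that makes the
prefactor η_pore A_drop A_Π collapse to the drop footprint area, leaving the
flux terms independent of an arbitrary control-volume size. It is
configurable.

## Numerical scheme

Node-centered uniform finite volumes (N_x = 100 cells by default),
second-order central differences with arithmetic face averaging of D,
Dirichlet values imposed at the boundary faces at half-cell distance. The
adsorption sink and the porosity time derivative are handled by the chain
rule, giving a per-cell diagonal "mass matrix" that is solved pointwise, so
the coupled system (2 N_x field states + 6 droplet/ledger states) is a stiff
explicit ODE system. It is integrated with SciPy's BDF method (rtol 1e−8,
atol 1e−12 defaults) with an analytic Jacobian sparsity pattern, in three
phases separated by terminal events: θ = θ_rec; drop end when the water
volume or the drop's AI content falls below 10⁻³ of its initial value (the
hygroscopic endgame is an asymptotic chase of V_Del → 0, so a relative
threshold is needed; the Popov V^{2/3} law makes the below-POD tail
contribution of this threshold ~1 % of the CCA duration). After the drop
ends, the outer AI boundary becomes zero-flux, the outer water boundary is
held at pure water, and cuticle-only diffusion continues to t_final — the
cuticle-transit timescale (b²/D_AI ≈ 90 s) is far below the drop timescale,
so the residual cuticle AI flushes quickly and the 48 h penetration series
plateaus, as a mass-based assay would record.

Mole bookkeeping: the drop content, bound moles, cuticle influx and bath
delivery are integrated as ODE states, so applied = drop + bound + cuticle +
bath closes to integrator accuracy (observed ≤ 1e−11 relative; tested at
1e−6) at every output time. Because the quasi-1-D model injects A_drop-
weighted fluxes into a per-area PDE, the "in-cuticle" ledger entry is the
cumulative net influx integral (a pointwise cuticle mole content under a
shrinking footprint is not well defined). Penetration mass uses the
ODE-integrated bath ledger; an independent trapezoidal reconstruction from
the stored bath-face flux series agrees to ~1 % on the output grid and is
kept as a cross-check.

Robustness choices: the drop concentration c = n/V is clamped to
[0, 5 c_POD] only to bound the rate when the integrator probes past a
terminal event; the surface water Dirichlet value is floored at zero (only
reachable transiently below the POD, where the real solution would
crystallize). Grid refinement N_x 100 → 200 changes the 48 h penetration by
< 1e−5 relative; halving the tolerances changes it by < 0.1 %.

## Parameters

All physical constants and the four calibrated parameters live in
`ModelParameters` (SI units internally; degrees, hours and g/L at I/O).
The calibrated values for CaCl₂ (+RSO 5) on tomato fruit cuticle at 20 °C:
F_s = 1.203 (−), k = 8.68e−16 m³/s, η_pore = 2.18e15 m⁻², χ = 0.043 L²/g²;
an alternative set (F_s = 1.138, k = 3.74e−15, η_pore = 1.99e15,
χ = 0.0023) that improves only the 150 µg surfactant fit ships as the
`cacl2_rso5_alt` preset. Initial contact angles come from the measured
initial contact areas of 1 µL drops at each applied concentration
(`CONTACT_ANGLE_TABLE`), inverted through the spherical-cap area relation to
better than 1e−8 relative; the receding-angle fraction 0.1264 is a config
constant. Measured areas are treated as t = 0 (post-spreading) states.

## Experiments layer

- `validation_suite` reruns the model over c₀ ∈ {1, 5, 10, 15, 30} g/L with
  the concentration-matched contact angle, sharing one calibrated parameter
  set, and summarizes the final percent penetration.
- `sensitivity_oat` applies one-factor-at-a-time perturbations around the
  1 g/L + RSO 5 baseline and ranks parameters by percent relative
  sensitivity at 48 h, residual sum of squares and RMSE over a common time
  grid; these are the standard OAT measures matching the reported column
  captions (the source's exact formulas are in unavailable supplementary
  material, so rankings — not magnitudes — are the comparison surface).
- `fit_parameters` minimizes pooled squared percent residuals by
  Nelder-Mead over smooth reparameterizations (logit for F_s ∈ (1,2), log
  for k, η_pore, χ ≥ 0), optionally staged (first dataset alone as a warm
  start, then jointly) as in the original calibration protocol. The
  design-of-experiments (Fedorov exchange) refinement of the original
  protocol is out of scope.
- `make_fixture` samples a simulated curve at the assay cadence, adds
  seeded Gaussian noise and clamps to [0, 100].
- `two_exponential_fit` characterizes a curve as
  a₁(1−e^{−t/τ₁}) + a₂(1−e^{−t/τ₂}) (τ₁ < τ₂). On simulated baseline
  curves the two timescales are *not* separated — the model's curve is
  sigmoidal because the drop first concentrates before transport peaks —
  and the fit falls back, flagged, to a single exponential. Separated
  timescales are recovered exactly on data that possess them.

## What the synthetic fixtures do and do not emulate

Fixtures are model curves plus independent Gaussian noise at the assay
cadence. They reproduce the sampling times, magnitude and noise scale of a
radiotracer/ICP penetration assay, but not: correlated within-replicate
errors, the spreading-phase ambiguity in the measured initial areas, or any
systematic model misfit. Passing the parameter-recovery tests therefore
demonstrates identifiability of (k, η_pore) under the model's own dynamics,
not accuracy against real cuticles; fitting real data requires digitized
experimental curves supplied by the user.

## Problem sizes used in the shipped tests

Unit and property tests run the full 48 h scenarios at the default
N_x = 100 resolution; fitting and statistics tests use a reduced
configuration (N_x = 24, 8 h horizon, rtol 1e−6) chosen so that the
recovery experiments still resolve the drop dynamics that identify the
parameters while keeping each optimizer evaluation around a second.

## Known limitations

- One representative pore radius per depth; no pore-size distribution,
  lamellae or 2-D/3-D structure.
- Ion binding is irreversible, surface-only, and linear in the drop
  concentration; remobilization and in-pore binding are not modeled.
- No gravity or contact-line physics beyond the two-mode CCR/CCA
  idealization; no stage-3 evaporation; no Marangoni/coffee-ring deposit
  morphology.
- Temperatures are fixed at 20 °C (densities, vapor pressure, POD).
- Crystallization below the POD is a hard threshold; efflorescence
  hysteresis is not modeled.
- Multiple drops are assumed identical and non-interacting (results scale
  linearly in n_drops).
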