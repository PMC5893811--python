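# Methods

## Problem and model

`laa_stasis` studies how the shape of the left atrial appendage (LAA)
conditions blood stasis — the precursor of thrombosis in atrial
fibrillation (AF) — by simulating pulsatile flow through a planar left
atrium (LA) + appendage geometry and measuring washout and shear
metrics in the appendage. Eight runs form the core experiment: the four
canonical LAA morphologies (chicken wing, cactus, windsock,
cauliflower) under a healthy and an AF boundary condition.

Blood is incompressible and Newtonian (ρ = 1060 kg/m³, μ = 0.0035
Pa·s), the regime laminar: the Reynolds number built from the peak
mitral velocity (0.32 m/s) and the mitral orifice diameter (25 mm) is
≈ 2400. Walls are rigid with no-slip; pulmonary-vein (PV) inlets are
open boundaries at reference pressure 0; the mitral orifice carries a
prescribed plug outflow waveform. The virtual contrast agent is a
passive, non-diffusive scalar initialized at 1 everywhere; clean (c = 0)
blood enters through the PVs and contrast leaves with the mitral
outflow, so its residual after four cardiac cycles is a residence-time
surrogate.

### Geometry

Patient anatomies are not available, so the anatomy module generates
parametric 2-D silhouettes: an elliptical atrial body (5 cm major
diameter, aspect 0.85) with

* a flat mitral chord (25 mm) at the bottom,
* 4–6 pulmonary veins on the upper arc, each a short stub channel
  (length 1.5 diameters) ending in the open inlet — placing the open
  boundary in quasi-one-dimensional flow as the real vein roots do,
* the appendage attached through an ostium chord on the left.

Appendage outlines are unions of buffered centerline segments and lobe
ellipses: a bent tapering tube (chicken wing, bend 100°), a central
tube with alternating side lobes (cactus), a long gently curved
tapering tube (windsock), and a short widening sac with peripheral
lobes and seeded irregularity (cauliflower). Lengths follow the
clinical 2–4 cm range; ostia are 18–22 mm; PV widths 7.5–11 mm
(clinical ostia are ~10–13 mm; the narrower values arise where six
veins must share the 2-D upper arc). A seed fully determines each
geometry. The ostium separating curve — which the integrals need but
clinical practice defines only loosely — is the explicit base chord of
the appendage frame; appendage cells are exactly those on its distal
side.

### Discretization

The mesh generator is distmesh-like: labeled boundary polylines
resampled at the target edge length h (sharp corners preserved), a
hexagonal interior lattice, Laplacian smoothing with Delaunay
reconnection, and culling of triangles whose centroid leaves the
domain. Default h = 1.2 mm gives ≈ 4–5.5 × 10³ triangles per anatomy
with minimum radius-ratio quality ≥ 0.4.

Momentum uses a first-order-in-time fractional-step (projection) scheme
on vertex-based P1 elements:

1. **Advection** — semi-Lagrangian with RK2 departure points and P1
   interpolation, plus MacCormack back-and-forth error compensation
   clamped to the interpolation stencil's min/max. The plain
   semi-Lagrangian step is first-order in space; the compensated scheme
   measures second order on a manufactured solution (observed 2.06)
   while remaining unconditionally stable and monotone.
2. **Viscosity** — implicit backward-Euler Helmholtz solve
   (M/Δt + νK, factorized once), with wall/mitral values imposed as
   strong Dirichlet rows; no diffusive time-step restriction.
3. **Projection** — the pressure Poisson problem is built from the
   exact discrete operator Gᵀ M⁻¹ G (lumped mass), not the stiffness
   matrix, so the post-projection weak divergence vanishes to rounding
   (~10⁻¹⁶ relative) at every free node; the solver raises if the
   configured tolerance (10⁻⁸) is ever exceeded. PV pressure Dirichlet
   values fix the gauge.

Open PV boundaries need two stabilizations, both standard: the
tangential velocity is constrained to zero at PV nodes (the inlet
carries only normal flow), and the Dirichlet pressure is the
*total*-pressure (directional do-nothing) value
p = −½ρ(u·n)₋² — entering fluid sees its static pressure lowered by
the dynamic head, which bounds the kinetic energy an open boundary can
inject. Without the second condition a PV inflow jet grows
exponentially once its local Courant number approaches one; with the
sign inverted (static pressure raised) the blowup is faster. Both
failure modes were observed directly; the switch
(`SolverConfig.open_boundary_stabilization`) stays on for atrium runs
and off in channel-verification problems whose inflow is already
controlled.

The contrast scalar is cell-centred finite-volume, advanced in flux
form with first-order upwinding. Edge fluxes are integrated exactly
from the P1 velocity and then passed through a small TPFA
flux-correction Poisson solve that zeroes every cell divergence
exactly (residual mass imbalance exits through the PV faces). On
divergence-free fluxes the upwind update is a convex combination, so
0 ≤ c ≤ 1 holds strictly, total contrast is conserved to rounding in
closed domains, and washout is monotone. The scheme subcycles
internally to its CFL bound. Numerical diffusion of first-order
upwinding spreads contrast fronts over a few cells; residual-contrast
percentages at this resolution are therefore upper bounds relative to
a sharp-interface transport.

### Boundary waveform

One cardiac cycle is T = 0.8 s: the mitral valve is closed for the
first 37.5% (atrial diastole), then atrial emptying fills the remaining
0.5 s with two smooth sin² pulses — the E-wave over [0.30, 0.70] s
peaking at 0.32 m/s (the cycle maximum) and the A-wave over
[0.70, 0.80] s peaking at 0.24 m/s (0.75 × E) at t = 0.75 s. Only the
peak value, period and phase split are published for the source flow
curve; the pulse shapes and the A/E ratio of 0.75 (clinically normal
E/A ≈ 1.3) are modelling choices. AF removes the A-wave (A peak set to
zero) and leaves the E branch untouched, so the two conditions
coincide outside the A-wave support and the AF cycle ejects exactly
the A-wave volume less.

### Metrics

* **SSR** — shear strain rate √(2 D:D), cell-wise from the exact P1
  gradient: 0 for uniform flow and rigid rotation, γ for simple shear.
* **Centerline** — appendage cells binned by geodesic distance from
  the LA/LAA interface; each station is the area-weighted centroid of
  its band, following the connected component of the previous station
  through multi-lobed sections; s ∈ [0, 1] is normalized arclength.
* **Profiles and LAA-normalized integrals** of |v| and SSR are
  averaged over the 16 recorded phases of the **last** cycle. The
  claims these support (decay from ostium to tip, depression under AF)
  hold throughout the cycle, and the phase average suppresses the
  sampling noise of meandering atrial vortices that any single instant
  carries in 2-D.
* **Residual contrast** — % of the initial scalar remaining at the end
  of cycle 4, normalized by domain volume (headline) and by appendage
  volume; **dye localization** — the c-weighted mean of s over
  appendage cells (1 = tip).
* **Periodicity** — relative L2 velocity difference between cycles 3
  and 4 over matched phases; the configured threshold 0.2 separates a
  phase-locked flow (forced through-flow repeats; only the weak vortex
  remnant drifts) from an unsettled one. Observed values in the default
  grid are 0.01–0.13 for seven of the eight runs; the healthy
  cauliflower run measures 0.215 — its wide multi-lobed sac holds the
  largest slow vortex remnant and has not fully phase-locked by cycle 4
  (the cycle-pair sequence still decays, 0.42 → 0.24 → 0.215). This is
  reported as-is rather than relaxing the threshold.

## What the synthetic data do and do not show

The generator reproduces the morphological *contrasts* the comparison
needs — bend, lobes, taper, length, ostium width, PV count — on a
planar silhouette at desk scale (≈5 × 10³ cells per run, minutes per
grid on one CPU). It does not reproduce patient-specific 3-D anatomy,
trabeculation, wall motion, or out-of-plane vortex dynamics; 2-D
vortices are longer-lived than 3-D ones, and absolute residual
percentages here (units of % of a 2-D area) are not comparable to
published patient values. Passing the trend checks therefore shows the
method ranks *shapes and conditions* consistently with the published
surface, not that it predicts any patient's numbers.

## Numerical choices and degenerate inputs

* Δt = 0.5 ms (as published) with 4 cycles; Δt must divide T.
  Semi-Lagrangian Courant numbers stay ≈ 0.4 at the defaults; a
  configurable guard warns (or raises) at 10.
* Pressure and Helmholtz systems are factorized once per run (SuperLU)
  — the matrices are constant.
* Departure points leaving the domain fall back to the nearest vertex
  value (no-slip walls make this exact in the limit).
* Meshes below radius-ratio quality 0.1 are rejected; degenerate
  (zero-measure) cells raise before any metric is computed.
* Empty regions, unknown labels, out-of-range concentrations, zero
  appendage dye and mismatched snapshot phases raise typed errors
  rather than propagating NaNs.

## Known limitations

* 2-D planar geometry; no wall motion (the paper's own rigid-wall
  simplification, which also approximates chronic-AF atria); no
  turbulence or transition modelling; Newtonian rheology.
* First-order upwind contrast transport is diffusive; washout
  percentages depend on resolution and should be compared only within
  a fixed resolution.
* The ostium separating curve is a modelling definition; integrals
  normalized "per appendage" inherit it.
* The Chorin splitting is first-order in time; pressure near open
  boundaries carries the usual splitting boundary layer.
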