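# Methods

## Scope and intent

`pulsarch` is a reduced-order model of pulsatile blood flow through an
aortic-arch-like network. It deliberately replaces the 3D curved
geometry with fully developed axisymmetric tube flow per branch: the
convective term then vanishes identically, every building block has a
closed-form oracle, and the effect of blood rheology is isolated
exactly — which is the comparison the package exists to make.
Curvature-driven secondary (Dean) flows, turbulence, wall compliance
and patient-specific geometry are out of scope by design.

## Constitutive model

Effective viscosity follows the Carreau form
`mu_eff = mu_inf + (mu0 - mu_inf) (1 + (lambda*gamma)^2)^((k-1)/2)`.
The Yasuda exponent is fixed at 2 (pure Carreau); no extra parameter
is exposed. Registered conditions:

| condition | k | lambda (s) | mu_inf (Pa·s) | mu0 (Pa·s) | hematocrit |
|-----------|------|--------|---------|--------|------|
| anemic    | 0.33 | 12.448 | 0.00257 | 0.0178 | 25 % |
| diabetic  | 0.39 | 103.09 | 0.00802 | 0.8592 | 65 % |
| healthy1  | 0.48 | 39.418 | 0.00345 | 0.0161 | ~45 % |
| healthy2  | 0.3568 | 3.313 | 0.0035 | 0.056  | ~45 % |

Density is 1060 kg/m³ throughout. Hematocrit is metadata only; it
does not enter the law. The 3D shear-rate scalar is the standard
second invariant `gamma = sqrt(2 D:D)` (simple shear du/dy = s gives
exactly s). Numerically the transition factor is evaluated via
`exp/log1p` with `lambda*gamma` clamped at 1e15, which preserves both
plateaus to well under 1e-6 relative. Note that the slow-transition
diabetic set is itself still ~5e-6 relative away from `mu_inf` at
gamma = 1e10 1/s — a property of the law, not of the implementation.

## Inlet waveform

Piecewise sinusoid/plateau with period 0.5 s, systole ending at
0.218 s, amplitude 0.5 m/s, diastolic level 0.1 m/s, phase offset
0.016 s, angular factor 4*pi rad/s. The phase offset makes the
waveform nearly continuous at both junctions (|jump| < 5e-3 m/s at
systole end, < 5e-4 m/s at cycle start). In-cycle time tau = 0 maps
to the diastolic branch, matching continuity; negative times extend
periodically. A zero amplitude degenerates to a constant plateau
(no systolic ejection), which is the steady-flow limit used in tests.
The cycle mean (closed form, 0.21235 m/s for defaults) sizes the
Windkessel resistances.

## Windkessel outlets

Three-element RCR per branch: P = Pc + R1*Q, C dPc/dt = Q - Pc/R2.
The discrete update is backward Euler with **beta = R2*C/dt** — the
dimensionless form. (A product R2*C*dt would carry units of s² and
makes the update dimensionally inconsistent; with the quotient the
update is the exact backward-Euler discretization of the RCR ODE, as
verified algebraically and against a Runge–Kutta oracle in the tests.)
The P-form and Pc-form of the update are algebraically identical and
cross-checked to 1e-12.

Parameter estimation: Rtot = Pmean/Qmean, R1 = 0.05 Rtot,
R2 = 0.95 Rtot, C = tau/R2. Defaults: Pmean = 13332 Pa (~100 mmHg)
and tau = 1.0 s; the capacitor starts at Pmean so the start-up
transient decays within a few cycles. Branch mean-flow fractions
default to brachiocephalic 0.15, left carotid 0.075, left subclavian
0.075, descending aorta 0.70 — package defaults at adult scale, as are
the branch radii (6, 4, 4, 10.5 mm; inlet 12.5 mm). All are
configurable and labelled as defaults in every output.

## Tube solver

Axial momentum in a rigid straight tube of radius R:
`rho du/dt = -dp/dx + (1/r) d/dr(r mu_eff(|du/dr|) du/dr)`, no-slip at
the wall, symmetry at the axis.

* **Spatial discretization**: node-centered uniform radial grid
  (default nr = 101), finite-volume face fluxes; the axis cell uses
  the half-cell volume dr²/8, which reproduces the regularized
  Laplacian limit. For constant viscosity the discrete steady solution
  is the exact parabola nodally, so the Poiseuille checks are limited
  only by the trapezoidal mean-velocity quadrature (O(dr²)).
* **Driving**: either the cross-section mean velocity is prescribed
  (the waveform) and the uniform dp/dx recovered as a bordered-system
  multiplier — two tridiagonal solves per pass via superposition — or
  dp/dx is prescribed directly (oracle mode).
* **Time integration**: theta scheme, default theta = 0.5
  (trapezoidal diffusion) with the pressure-gradient source evaluated
  at the step midpoint and a fully implicit first step; theta = 1
  gives backward Euler. The midpoint source matters: an explicit
  old-source term makes the constraint multiplier ring undamped after
  the waveform's slope breaks, whereas the midpoint form is
  second-order and quiet. Default dt = period/1000.
* **Nonlinearity**: Picard (lagged-viscosity) iteration, relative
  tolerance 1e-8, max 50 passes; for constant-viscosity runs it
  terminates after one pass. Non-convergence raises an error carrying
  the residual history.
* **Wall shear stress**: one-sided second-order difference at the
  wall (exact for parabolas), viscosity evaluated at the wall shear
  rate, reported as a magnitude.

Measured fidelity (also asserted in the tests): 0.1% relative L2
velocity error and 0.5% peak-normalized WSS error against the
analytic oscillatory (Womersley) solution at nr = 201, dt = T/2000,
Womersley number alpha ≈ 24; 0.1% against Poiseuille in the steady
limit. WSS error is normalized by the cycle-peak analytic WSS because
pointwise relative error is ill-defined near the oscillatory zero
crossings.

## Arch pipeline

Inlet flow Q_in(t) = v(t)·pi·R_inlet²; branch flows are fixed shares
of Q_in, so junction mass balance holds exactly by construction. Each
branch runs the tube solver (for velocity profiles, dp/dx and WSS) and
a Windkessel (for pressure). Eight cycles are simulated by default and
the last is reported after a periodicity check against its
predecessor (relative L∞, threshold 0.5%); the tube march starts from
the steady profile at the cycle-mean velocity, which removes most of
the slow viscous transient (decay rate ~ nu (2.405/R)², i.e. tens of
cycles if started from rest). The residual periodicity error is
dominated by the Windkessel capacitor transient (~0.2% after 8
cycles with default tau).

Because the flow split is prescribed, branch *pressures* are identical
across blood conditions in this model; rheology expresses itself in
the pressure gradients and WSS. A pressure-coupled junction that
would feed viscosity back into the flow split is a known non-goal.

There is no randomness anywhere in the pipeline; identical
configurations give bitwise-identical outputs.

## Diagnostics and classification

Helicity density H = u·(curl u) is evaluated with second-order central
differences (one-sided second-order at boundaries, or periodic
wrapping for periodic analytic fields — wrapping is used for the
Beltrami oracle, whose helicity equals |u|² pointwise). Summaries are
exact min/mean/max.

Severity bands (traffic-light): for WSS, the cycle-average green band
0.4–1.5 Pa is the established physiologic range; the max cutpoints
(1.5 / 4.5 Pa) and min cutpoint (0.05 Pa) are illustrative package
defaults. Pressure bands map min/max/avg to diastolic/systolic/MAP
norms (60–90 / 90–140 / 70–105 mmHg) and are likewise illustrative.
Values exactly on a band edge take the lower-severity side
(conservative). Every report embeds the bands used and an
"illustrative" note.

## Synthetic references

All oracles are deterministic closed forms: Womersley
(complex-Bessel, with analytic mean velocity and wall shear),
Poiseuille, the ABC Beltrami field on the periodic cube (sampled
without the duplicate endpoint so finite differences can wrap), and
solid-body rotation. The default network generator wires the four
branches with estimated Windkessel constants so that Rtot_i·Q̄_i
equals the target mean pressure exactly.

## What the synthetic conditions do and do not show

The generators emulate the *study conditions* — the four rheology
sets, the printed waveform, the 5/95 resistance split with tau = 1 s —
not patient data. Passing tests therefore demonstrate correctness of
the constitutive law, the boundary models and the reduced solver, and
reproduce the qualitative cross-condition orderings (diabetic >
healthy > anemic in viscosity, peak |dp/dx| and cycle-averaged WSS).
They do not reproduce 3D-geometry effects (curvature, branch-root
WSS hot spots, helical secondary flow in the arch) and the absolute
WSS/pressure magnitudes depend on the assumed branch radii.

## Problem sizes

Defaults: nr = 101 radial nodes, dt = T/1000, 8 cycles. The test
suite and ordering/periodicity checks run at nr = 41–81,
dt = T/250–T/500 and 5–8 cycles, resolutions at which the asserted
properties are converged (the self-convergence test bounds the dt
sensitivity of cycle-averaged WSS at well under 0.5%). The
Womersley fidelity checks use nr = 201, dt = T/2000.

## Known limitations

* Fixed flow split: no pressure-equalizing junction; branch pressure
  is rheology-independent by construction.
* Straight rigid tubes: no curvature, tapering, FSI or turbulence.
* The severity classification is comparative/illustrative, not a
  validated clinical instrument.
* Carreau rheology only: no yield stress (Casson/Herschel–Bulkley) or
  thixotropy; hematocrit is descriptive metadata.
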