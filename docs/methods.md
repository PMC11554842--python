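# Methods

`biofilmsim` simulates the growth of a homogenized, single-species
biofilm as a coupled multi-physics problem on a fixed reference domain:
a phase field for the biofilm density, a quasi-steady nutrient
concentration, a local volumetric expansion variable, and quasi-static
incompressible hyperelasticity with a multiplicative growth split.
This note records the model as implemented, the numerical choices, and
their known limitations.

## State variables

| symbol | meaning | discretization | range |
|---|---|---|---|
| phi | biofilm density (1 = dense biofilm, 0 = void) | nodal, trilinear | [0, 1] |
| c | nutrient concentration (normalized) | nodal, trilinear | [0, 1] |
| u | displacement (um) | nodal, trilinear | — |
| p | hydrostatic stress (Pa, tension +) | constant per element | — |
| alpha | local expansion parameter | internal, 8 Gauss points/element | >= 0 |

Time is normalized: T* in [0, 1] spans the growth episode; no attempt
is made to assign physical hours.  All PDEs are posed on the reference
configuration; coordinates are material coordinates in micrometres.

## Evolution equations

Per unit normalized time,

    dphi/dt  = beta lap(phi) + k_alpha alpha
               - |grad phi| (r c/(k + c)) (n_phi . n_c)
    dc/dt    = d lap(c) - g phi s(c)
    dalpha/dt= k_alpha phi

with zero-flux boundaries for both fields, c = 1 held on the
case-specific source set, and n_phi, n_c the unit gradients of phi and
c.  The Monod factor r c/(k+c) saturates in nutrients; the orientation
factor n_phi . n_c biases interface motion toward the steepest nutrient
gradient, and the |grad phi| weight confines this "non-local" growth to
the biofilm/void interface.  The k_alpha alpha term is local
density-based growth; alpha itself integrates the local biofilm history
and feeds the mechanical growth split.

`s(c) = c/(c + c_shutoff)` is an exhaustion regularization of the
consumption sink (see *Numerical choices*).

One-way coupling: the mechanical state does not influence growth (the
elastic feedback term phi mu (I:Ce - 3) in the phi equation is
negligible at mu ~ Pa against growth terms of order 10^2..10^8 and is
disabled by default; a `mech_coupling` flag restores it for sensitivity
studies).  Mechanics is therefore a post-state of each substep and is
solved at a configurable cadence.

## Parameters

Baseline constants (viscosity-normalized; `MaterialParams` defaults):

| parameter | value | units |
|---|---|---|
| shear modulus mu (E = 10 Pa, nu = 0.49) | 3.3557 | Pa |
| nutrient diffusivity d | 1e10 | um^2/T* |
| phase-field regularization beta | 2 | um^2/T* |
| growth factor k_alpha | 1e-3 | 1/T* |
| half-velocity constant k | 1 | — |
| consumption parameter g | 1e8 | 1/T* |
| growth parameter r | 100 | 1/T* |

The maze geometry (560 um diameter) uses d = 1e13, beta = 10,
k_alpha = 1e-6, r = 200 (`MaterialParams.maze_defaults()`); a config
with `case: maze` applies these automatically.

Numerical constants: `eps_grad = 1e-8` (gradients below this are
treated as exactly zero in the orientation term — far below any
physical gradient at >= 1 um spacing); `stiffness_floor = 1e-3`
(ersatz void stiffness, below); `c_shutoff = 0.01` (consumption
shutoff, below).

## Kinematics and mechanics

The deformation gradient splits multiplicatively, F = Fe Fg, with an
isotropic stress-free growth map.  The growth stretch is 1 + alpha, so

    Fg = (1 + alpha) I,   Fe = F / (1 + alpha),

which is regular at the natural initial state alpha = 0.  The strain
energy is an incompressible neo-Hookean law weighted by the biofilm
density,

    Psi = phi^2 (mu/2) (I : C~e - 3) + p (det Fe - 1),

with C~e = (det Fe)^(-2/3) Ce the isochoric elastic Cauchy-Green
tensor.  Evaluating the energy on the isochoric invariant (they agree
once det Fe = 1) makes the stress-free grown state carry p = 0, so the
recovered multiplier is interpretable as hydrostatic stress without a
-mu phi^2 offset.  The quadratic phi weighting leaves the void without
stiffness; assembly floors it at phi^2 + 1e-3 so the global system
stays definite where phi = 0 (an ersatz-stiffness regularization; the
incompressibility constraint remains active everywhere).

The element is the classical Q1P0 brick: trilinear displacements,
2x2x2 Gauss quadrature, one constant pressure per element enforcing the
element mean of det Fe = 1.  With the exact multiplier the pressure
diagonal of the element tangent is structurally zero, so per-element
static condensation is impossible; the default solver assembles the
global saddle-point system in (u, p) and factorizes it directly, which
is robust at the problem sizes this package targets.  A
perturbed-Lagrangian variant (energy term -p^2/(2 kappa), finite
`kappa`) makes the pressure block invertible and enables the textbook
Schur-complement condensation; the two routes solve the same perturbed
problem and agree to solver precision, at the cost of approximate
incompressibility |det Fe - 1| ~ |p|/kappa.

Mechanical boundary conditions for the box cases are minimal 3-2-1
rigid-body pins on a free outer boundary: exact incompressibility plus
a growing volume requires a free surface (a fully pinned boundary is
volumetrically infeasible, which the solver detects and reports).
Rigid obstacles and maze walls are inactive elements; their surfaces
impose frictionless sliding as zero normal displacement on the shared
faces (axis-aligned by construction).  Semi-2D cases fix the
out-of-plane displacement everywhere.

The global problem is solved by Newton iteration with an analytic
consistent tangent (verified against finite differences to ~1e-9
relative); at the growth magnitudes of the baseline parameter set
(alpha <= k_alpha T* ~ 1e-3) it converges in 1-3 iterations.

## Time stepping

A run advances with a staggered update per substep, fast field first:

1. nutrients: backward Euler; the system matrix (mass/dt + d K) is
   constant, the consumption diagonal is linearized about the previous
   substep's c,
2. phase field: backward Euler, implicit diffusion and implicit Monod
   advection built from the *fresh* nutrient gradient (a
   `lag_gradient` flag retains the variant that lags the gradient by
   one substep),
3. alpha: per Gauss point, backward Euler on dalpha/dt = k_alpha phi
   (default); an increment-driven variant
   (a1 - a0)/((1+a1) dt) = k_alpha (phi1 - phi0)/dt with closed form
   a1 = (a0 + K)/(1 - K) is available as `variant="table1"`.  The two
   variants are *different* laws (value-driven vs increment-driven);
   each converges at first order to its own continuum limit,
4. mechanics at the configured cadence.

The nominal substep is t_end/1000; any solver failure (singular
system, non-convergent Newton, inverted element, K >= 1 in the
increment variant) halves the substep and retries, up to the
equivalent of 10^6 substeps, after which the run aborts preserving the
last good state.  The model is deterministic; a seed field is recorded
for provenance only.

With d = 1e10 um^2/T* on 20 um domains the nutrient field is
effectively quasi-steady (diffusion time ~4e-8 T*): each substep's c is
the steady balance of source, diffusion and consumption for the current
phi, which realizes the time-homogenization assumption (fast diffusion,
slow growth) without a separate steady solver.

## Numerical choices

**Consumption at exhaustion.**  The bare linear sink g phi keeps
consuming where c has already reached zero.  In the quasi-steady limit
the linear solve then couples those regions to the whole domain and
drags the concentration field far negative everywhere — clamping the
result cannot undo the global drag, and the nutrient plume collapses to
the immediate neighbourhood of the source.  The implemented sink
g phi c/(c + c_shutoff) is the paper-rate g phi wherever nutrients
remain (c >> c_shutoff = 0.01) and shuts off as they are exhausted,
i.e. a regularization of the complementarity condition "consumption
only where nutrients exist".  `c_shutoff = 0` restores the bare law.
Fields are clamped onto [0, 1] after every substep in either case.

**Galerkin advection.**  The orientation term is a non-conservative
advection of phi at speeds up to r/(k+1) ~ 50 um/T*; at 1 um spacing
and beta = 2 the element Peclet number is ~12.  No SUPG/upwind
stabilization is applied (the beta-diffusion regularizes and the
[0, 1] clamp bounds over/undershoots); consistent mass is the default
and row-sum lumping is available (`lumped_mass=True`), which restores
the discrete maximum principle for the pure-diffusion limit and is used
in the exact mass-conservation test.

**Gauss-point/node transfer.**  alpha lives at Gauss points; the
k_alpha alpha source of the phi equation and the VTU output use a
volume-weighted transfer to nodes (lumped L2 projection).

**Linear solvers.**  Both field systems are a constant matrix plus a
slowly drifting part.  The constant part is LU-factorized once per
step size; the nutrient system (symmetric positive definite after
eliminating Dirichlet rows symmetrically) is solved with conjugate
gradients preconditioned by that factor, the phase-field system
(nonsymmetric, mass-dominated) with LU iterative refinement.  Both
check the true residual to 1e-11 relative and fall back to a direct
factorization if the iteration stalls.  Everything is deterministic:
identical inputs reproduce identical trajectories bit for bit.

## Boundary value problems

Five built-in cases (`make_bvp`), geometry generated programmatically:

- `cube_directional` — 20^3 um box at 1 um spacing; phi = 1 in the
  central radius-5 um sphere; c = 1 on a corner patch.  The source
  extent is not fixed by the original description; the default is a
  patch of radius 5 um (the case's characteristic feature size) because
  a single corner node cannot supply the colony's consumption demand
  (g V ~ 5e10/T* against a point-source conductance ~ d h = 1e10/T*)
  and leaves the simulation inert.  `corner_radius` overrides it.
- `agar` — same box; c = 1 on the whole bottom face, phi = 1 in a
  5 um-diameter disc in the node plane directly above.
- `obstacles` — 30^3 um box; four rigid columns (diameter 6 um, at the
  quarter points — the source geometry is not restated in the original,
  so positions and diameter are configurable) excluded via the active
  mask; colony sphere at the center; c = 1 on the bottom face.
- `maze` — semi-2D (one element thick, 4 um), overall diameter 560 um,
  10 um walls: a parametric generator of concentric ring corridors with
  one wall opening per ring (golden-angle placement) and one blocker
  opposite it, so every ring is a pair of dead-ends; c = 1 in the
  central chamber, colony at the outermost opening.  It reproduces the
  stated dimensions and topology class, not any particular drawing.
- `grate` — semi-2D (1 um thick) square lattice of 10 um channels
  between 10 um blocks; colony along one edge, c = 1 on the opposite
  edge.

Initial colonies are initial conditions only; a `phi_held_fixed` flag
holds them at phi = 1 for the alternative reading of the setup.

## What the built-in cases do and do not show

The cases are the package's synthetic experiments; all inputs are
generated, nothing is measured from real biofilms.  Passing tests
demonstrate the solver's structural correctness (conservation, bounds,
oracle equivalence, analytic mechanics limits, symmetry) and the
model's qualitative phenomenology: growth directed toward nutrient
sources, depletion-limited equilibria, growth around rigid obstacles,
dead-end retraction, compression inside the growing body with a tension
band at its interface.  They do not validate the model against
experimental data — the original parameters are phenomenological, time
is normalized, and absolute stress magnitudes depend on an unfitted
Young's modulus, so only sign patterns of p are meaningful.

Two quantitative anchors are tracked end to end at full resolution
(`scripts/acceptance.py`): the cube case's final domain-mean nutrient
concentration and the agar case's fill time (earliest T* with
phi >= 0.8 at every node, the same 0.8 level used to render the
biofilm body).  Both are sensitive to modelling choices the original
description leaves open.  The measured cube equilibrium sits near 5%
(against "around 10%" for the original): it scales with the
corner-source extent, which is only known pictorially.  The agar fill
time has a hard kinematic bound in this model: the interface speed is
at most max_c [r c/(k+c)] = 50 um/T* at r = 100, k = 1, so filling a
20 um cube from the bottom plane cannot complete before T* ~ 0.4 for
any sub-case, and a 13%-of-time fill is unreachable with the stated
constants; the simulated thin film additionally disperses below the
0.8 density level (its body is advected toward the nutrient face and
rarefied faster than the clamp can consolidate it), so the domain never
fills at that threshold.  The run reports the honest outcome; the
discrepancy is documented rather than absorbed into parameter changes.

## Known limitations

- No advective nutrient transport, detachment/erosion, gravity, or
  multi-species interactions.
- Frictionless contact is approximated by axis-aligned sliding
  constraints on obstacle faces; large sliding and self-contact are out
  of scope (the field formulation sidesteps self-contact of merging
  fronts).
- The phase-field advection is unstabilized Galerkin; thin (one-node)
  initial films at element-scale resolution lose density by numerical
  dispersion and model-inherent rarefaction, as discussed above.
- alpha has no upper bound (no growth homeostasis); extreme swelling
  eventually inverts elements, which the solver reports via bisection
  and abort.
- Mechanics solves use a direct sparse factorization of the global
  (condensed or saddle-point) system; this is sized for the built-in
  cases (<= a few 10^4 DOFs), not for large production meshes.
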