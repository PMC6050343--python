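# Methods

`icpkit` models a microfluidic preconcentrator: a shallow straight
channel (1 cm x 17 um by default) with a cation-permselective polymer
membrane printed as a 400 um x 6 um band on the top (PDMS) wall, filled
with 10 mM NaCl and driven by a DC axial field.  Under bias the membrane
transports cations preferentially, so an ion-depleted zone forms on the
anodic side and an enriched zone on the cathodic side (ion concentration
polarization, ICP).  Charged analytes carried towards the depletion zone
by electroosmosis are repelled by it electrophoretically and stack into
a concentrated plug, which accelerates enzymatic assays run in the
channel.  The package contains (i) a steady 2D
Poisson-Nernst-Planck-Stokes (PNP-NS) solver for the carrier
electrolyte, (ii) post-processing of the ICP observables and a frozen-
field tracer-transport model of the preconcentration itself, and
(iii) the downstream assay analysis (progress-curve kinetics, fold
changes, assay CVs, concentration bracketing) together with a calibrated
synthetic plate-data generator.

## Governing equations

Steady ion transport for the two ionic species (molar flux: diffusion,
electromigration, advection):

    div J_s = 0,   J_s = -D_s grad(C_s) - (z_s F / RT) D_s C_s grad(phi) + u C_s

Poisson with the membrane's immobile charge:

    -div(eps grad(phi)) = rho_e = F (z+ C+ + z- C- + N 1_membrane)

Creeping flow with the electric body force (inertia dropped; Re << 1 at
channel scale) and incompressibility:

    0 = -grad(P) + mu lap(u) - rho_e grad(phi),   div u = 0

Boundary conditions: reservoir concentrations (10 mM) and potentials
(field x length at the inlet, 0 at the outlet) at the two channel ends;
zero ion flux and zero normal field at the walls; electroosmotic slip
u_t = -(eps zeta / mu) E_t on the polystyrene bottom (zeta = -60 mV) and
PDMS top (-40 mV) walls, with the tangential field E_t evaluated from
the converged potential gradient at the wall; no-slip and no-penetration
on the membrane surfaces; zero velocity inside the membrane.

## Membrane model

The membrane is a porous volumetric region with

* uniform immobile charge `fixed_charge_concentration` (default
  -100 mol/m^3 = -10 c0, strongly permselective),
* a hard zero-anion-flux condition on every membrane face
  (`cation_only=True`); the anion concentration inside the membrane is
  then pinned at its ideal Donnan value (C+C- = c0^2, C+ - C- = |N|),
* an internal ion diffusivity reduced by `diffusivity_factor` relative
  to free solution (porosity/tortuosity of the printed polymer film).

The fixed-charge magnitude and the internal diffusivity of the printed
film are not measurable from the published device, and they control how
strongly the channel polarizes: the membrane branch conductance scales
like `diffusivity_factor x |N|`.  The default
`diffusivity_factor = 0.01` was calibrated so that the simulated anodic
depletion at the reference operating point matches the reported ~2 mM
level; it sits in the range of ionic diffusivities measured in hydrated
polymer films (one to two orders below aqueous).  Both parameters are
exposed in the config, and the acceptance tests sweep the fixed charge
to show the reported depletion is bracketed rather than asserted.

## Flow boundary condition at the reservoirs

With both reservoirs pinned to equal pressure, wall electroosmosis
drives a net through-flow of order 100 um/s, which makes the anodic bulk
advection-dominated: the concentration stays at c0 up to a thin front
near the membrane.  A microwell reservoir of finite volume cannot
sustain that flow at steady state: the liquid levels shift until the
opposing pressure head cancels the net electroosmotic flux, leaving only
the recirculating part of the flow (wall-driven slip plus pressure-driven
backflow in the core - which is also what produces the back-flow vortex
at the membrane).  The default `flow_bc="zero_net_flow"` imposes exactly
this: the Stokes block is solved once with the electric/slip forcing and
once for a unit reservoir head (both reuse one LU factorization), and
the head is chosen to zero the net flux.  In this regime the
cross-section-averaged salt transport is quasi-diffusive, which is what
makes the anodic profile close to linear.  `flow_bc="open"` restores the
equal-pressure behaviour.

## Discretization

Finite volumes on a structured rectilinear mesh; faces are always placed
exactly on the membrane rectangle.  Ion fluxes use Scharfetter-Gummel
exponential fitting for the combined diffusion/electromigration part
(exact for 1D constant-coefficient drift-diffusion, monotone at steep
depletion fronts) and first-order upwinding for the advective part.
The Stokes block is a standard staggered (MAC) discretization with the
pressure fixed by the open reservoirs; solid (membrane) cells enter as
identity rows, and no-slip on membrane-fluid interfaces is imposed
through half-cell ghost values.  Optional geometric grading refines the
mesh towards the membrane edges (in x) and towards the walls/membrane
interface (in y); grading = 1 gives uniform spacing.

### Debye-length rescaling

The physical Debye length at 10 mM is ~3 nm and cannot be resolved on a
17 um channel.  The Poisson coefficient therefore uses an inflated
Debye length, the standard device-scale rescaling for ICP simulation.
Two consistency rules keep the physics right: the electroosmotic slip
coefficient always uses the physical permittivity, and the electric body
force keeps the physical electrohydrodynamic coupling by scaling the
force coefficient with 1/debye_scale^2 (the force arising from the
numerically thickened space-charge layer would otherwise be amplified by
the square of the inflation).  The generic default inflates lambda_D to
span two of the smallest cells; the reference device case fixes
`debye_scale = 150` (lambda_num ~ 0.46 um, a few percent of the gap
height) so that results do not drift with mesh grading.  The tests
exercise the sensitivity of the depletion level to this knob.

## Nonlinear solution strategy

The coupled system is solved by a nested iteration:

1. **PNP block Newton.**  The (C+, C-, phi) equations are solved by a
   damped Newton method with an analytic sparse Jacobian at frozen
   velocity.  Steps are shortened to keep concentrations positive, and a
   backtracking line search enforces residual descent.  Linear systems
   use a sparse direct LU factorization by default (robust for the
   ~10^4-10^5 unknowns of practical meshes); restarted GMRES with an ILU
   preconditioner is available via `SolverSettings.linear_solver`.
2. **Stokes solve.**  The momentum/continuity block is linear in
   (u, P) at frozen charge and potential and is solved exactly; its
   operator depends only on the mesh, so it is factorized once per case.
3. **Outer fixed point.**  Steps 1-2 alternate (velocity under-relaxed
   by 0.7) until the velocity is stationary and the full residual over
   all unknowns is converged.
4. **Voltage continuation.**  The applied field is ramped through a
   geometric ladder of fractions of the target (the full drive is ~280
   thermal voltages over the 2 mm reference domain), each step warm-
   starting from the last converged state; failing steps are bisected.
   The steady state is path-independent, which the tests verify.

Convergence is declared on the rms of the scaled residual (default
1e-9); all equations are nondimensionalized (lengths by the channel
height, concentrations by c0, potential by RT/F, velocity by the
electroosmotic scale eps (RT/F) E / mu, pressure by mu u_ref/H).  The
velocity scale printed on the reference flow field (31.3 um/s) is not
derivable from the stated parameters; this package documents its own
electroosmotic reference (~65.5 um/s at the default field) instead of
forcing a match.

## Tracer transport and preconcentration factor

The trace analyte (default: a DNA-like species, z = -10,
D = 1e-10 m^2/s) is dilute and does not feed back on the carrier.  Its
transient advection-diffusion-electromigration equation is integrated on
the frozen converged (u, phi) fields by implicit Euler with a constant
operator (one LU factorization, automatic sub-stepping when the
advective Courant number of the requested step exceeds 5).  The face
flux folds the advective Peclet number into the exponential-fitting
potential together with electromigration; this "complete" exponential
scheme is exact for the steady 1D constant-coefficient problem, which is
what lets a drift-against-wall accumulation test hit exp(vL/D) to a
percent on an affordable mesh (plain upwinding would add numerical
diffusion comparable to D itself at these Peclet numbers).  The
preconcentration factor is reported as the field maximum over the
initial concentration; the experimental estimator (reference-intensity
comparison) is implemented separately as `pcf_from_reference`.  The
experimentally reported PCF (~10^3) depends on device details outside
this model (channel depth, detection optics, membrane microstructure)
and is not asserted.

## Assay analysis

Michaelis-Menten kinetics enter through v = v_max c_s/(k_m + c_s) with
v_max = k_cat c_enzyme; at saturating substrate the rate is proportional
to the locally concentrated enzyme, which is the mechanism of assay
acceleration.  Progress curves are fit with ordinary least-squares
quadratics y = a t^2 + b t + c and rates are the analytic derivative
y' = 2 a t + b, with an explicit time-unit tag ("min"/"h") because the
published rates mix per-hour and per-minute units.  "Net signal" is
I(t) - I(0) per well; fold changes compare net signals at matched times
against the negative control.  Intra-assay CV is the mean over
(device, concentration) groups of the replicate sd/mean; inter-assay CV
is the mean over concentrations of the CV across devices of the
device-group means (standard immunoassay QC definitions; the reference
experiments quote only the two summary values).  Concentration bracketing returns
the two reference standards flanking an unknown's net signal, with an
optional log-linear point estimate; signals outside the reference span
yield an explicitly open-ended bracket.  Kruskal-Wallis (tie-corrected,
chi-square approximation; seeded permutation variant for very small
groups) delegates the rank statistic to scipy.

## Synthetic plate generator

One well's fluorescence is

    I(t) = q [I0 + A(1 - exp(-t/tau)) + a(c) t^2 + b(c) t]
             (1 + eta_device)(1 + eta_well)

* The saturating-exponential background models free fluorophore in the
  reaction reagent; tau = 1 min puts the residual growth after 5 min
  below 1% of A, matching the observed negative-control plateau.
* The 300 ng/mL growth coefficients equal the published accelerated-fit
  derivative (2a = 1017.94, b = 160.63 RFU/min); 3 and 30 ng/mL share
  that b/a shape and are solved from the published fold-change triple
  (1.5, 3.8, 7.3) at 8 min, and the NC amplitude A follows from the
  7.3-fold equation.  Noise-free fold changes are therefore exact by
  construction, and the absolute RFU scale is arbitrary up to these
  calibrated ratios.  Intermediate concentrations interpolate a(c)
  log-log between the anchors.
* Both noise terms are multiplicative gains drawn once per device and
  once per well and held constant over the 8-minute course - the
  physical source is printing-induced membrane-thickness variation,
  a static property of each channel.  sigma_well is the intra-assay CV
  (9.80%).  The device std solves
  sigma_d^2 = inter^2 - intra^2/n_replicates (= 7.57% at the defaults)
  so that the *estimator* "CV across devices of replicate means" is
  centred on the nominal 9.45%; without this shrinkage correction the
  estimator would read ~11% by construction.  Small-sample sd bias
  (c4(3) ~ 0.886) makes the recovered intra-assay CV ~11% low in
  expectation; this is a property of the plain sd/mean estimator, kept
  because the worked examples define it that way, and it stays inside
  the 15% recovery band the tests enforce.
* A scalar quench factor q (default 0.85) models phenol-red quenching in
  medium-containing wells; the source shows the effect but quotes no
  number.

What the generator does *not* emulate: image-level structure of the
fluorescent plug, evaporation/bubble artifacts, plate-edge effects, or
time-correlated drift.  Tests passing on this generator therefore
validate the estimators' statistical behaviour under the stated noise
model, not robustness to instrument systematics.

## Problem sizes used by the shipped analyses

The reference ICP case runs on a 2 mm x 17 um channel (the full device
is 1 cm, but the ICP structure is local to the membrane; the shorter
domain keeps the full membrane and both bulk regions) at 200 x 40 cells,
uniform spacing, which converges in a few minutes on one core.  Assay
statistics use 200 seeded plates of 12 devices x 4 concentrations x 3
replicates.  The tracer oracle uses a 600 x 2 quasi-1D mesh.

## Known limitations

* The Debye rescaling makes near-membrane space-charge structure
  (and hence vortex intensity) a resolution-controlled quantity; only
  trends and bulk observables should be read quantitatively.
* The overlimiting / electroconvective-instability regime is out of
  scope (the reference case does not reach it), as are 3D effects,
  transient plug dynamics and AC driving.
* The block Gauss-Seidel coupling converges for the underlimiting cases
  exercised here; a monolithic Newton would be needed near limiting
  current.
* Donnan pinning of the membrane anion assumes ideal equilibrium with
  the bulk; activity corrections are ignored at 10 mM.
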