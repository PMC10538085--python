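# Methods

This note documents the models implemented in `pillartrap`, the numerical
choices behind them, and what the synthetic benchmarks do and do not show.
Units throughout: lengths in µm, stresses/pressures in Pa (so forces come
out in pN), flow rates in µL/min, SI for the flow fields.

## The critical-pressure power law

The package's central quantity is the critical pressure `Pc`: the minimum
driving pressure at which a deformable cell squeezes through the gap `g`
between two rigid micropillars instead of staying trapped.  The calibrated
closed form is

    Pc = c · E · (a/g)^n,      c = 0.027,  n = 2,

with `E` the cell's effective Young modulus and `a` its diameter.  `Pc` is
exactly linear in `E` (the trap is rigid and the load enters through a
pressure, so scaling stiffness and pressure together leaves the problem
unchanged) and depends on the lengths only through the ratio `a/g`.

`fit_power_law` estimates `(c, n)` from sweep data by ordinary least
squares on `log Pc − log E` against `log(a/g)`: the power law becomes
linear, the fit weights relative errors equally across decades, and the
free-exponent problem is convex.  A nonlinear least-squares objective on
the pressure scale (`objective="nls"`, multi-started over exponents in
[0.5, 4]) is available for sensitivity checks.  `R²` is always reported on
the untransformed pressure scale, because competing exponents are compared
on pressures; the residual standard error is reported on both scales, since
published fit statistics of this kind are often quoted without units.
Records with `Pc = 0` (free passage, `a ≤ g`) carry no information about
the power law and are excluded from fits with a logged warning.
`compare_model_orders` fits fixed exponents {1, 2, 3} and ranks them by
`R²`, breaking ties toward the lower order.

`validate_against` scores the model against measured `(gap, Pc)` pairs as
the coefficient of determination of observed vs. predicted values about the
identity line (not a refit), plus the Pearson correlation between them.

## Parabolic loading

The hydrodynamic push of the carrier flow is modelled as a parabolic
pressure field acting along the flow axis on the cell's upstream half:

    p(y, z) = P0 · (1 − (y² + z²)/r²),

with `r` the cell radius and `(y, z)` measured from the instantaneous cell
centroid, so the load travels with the cell; the factor is clamped to zero
outside the disk.  The "front region" is taken to be the upstream
hemisphere — surface locations with `x` at or behind the centroid —
re-evaluated every load increment.  Tractions act along the fixed `+x`
axis (no follower load), and each surface triangle contributes its
flow-projected area, so the resultant over a hemisphere equals the disk
integral `P0 π r² / 2` exactly in the continuum limit.  `Pc` is reported
as the peak value `P0` of this field.

## Contact simulation

The cell is a homogeneous neo-Hookean sphere:

    W = C10 (Ī₁ − 3) + (1/D1)(J − 1)²,
    C10 = E / (4(1+ν)),   D1 = 6(1−2ν)/E,   ν = 0.3,

meshed by a "spherified cube" of linear tetrahedra (a structured lattice on
the cube mapped radially onto the ball, six tets per hex), rescaled so the
discrete volume matches the sphere volume exactly.  Linear displacement
elements are adequate here because ν = 0.3 is far from incompressibility,
so no locking stabilization is needed; the default lattice resolution is
4 divisions per axis (125 nodes, 384 tets), a deliberate desk-scale
compromise — the acceptance properties rest on thresholds and exact
invariances, not on resolved stress fields.

The pillars are rigid diamond prisms with filleted vertices, represented
by an exact signed-distance field: the filleted diamond is the offset of an
edge-inset diamond, so its distance field is the polygon distance minus the
fillet radius.  Pillar centres are placed so that the minimum clearance
between the two *rounded* surfaces equals the requested gap exactly.  The
cell never reaches the channel floor or ceiling (cell diameter < pillar
height), so contact uses the 2D cross-section distance at every height.

Contact is frictionless and enforced by a penalty on the signed distance of
surface nodes, with stiffness `100·E / (mean surface edge)`; whenever the
residual penetration after an increment exceeds 1% of the gap, the penalty
is escalated fourfold (up to three times) and the increment re-solved.

### Quasi-static damped marching

Each increment minimizes the total potential with L-BFGS:

    Π(x) = elastic(x) + contact(x) − f·x + (η/2) Σᵢ wᵢ |xᵢ − xᵢ_prev|²,

where `f` is the (frozen) parabolic load and the last term is pseudo-time
damping with lumped nodal volumes `wᵢ`.  A free body under a pressure load
has no static equilibrium until contact balances the load; the damping
turns rigid drift into a controlled march, capped at 0.35 cell radii per
increment.  The damping coefficient adapts: slow, steady creep loosens it
(up to 8×), backward motion or overshooting tightens it.  After the load
ramp (8 increments) the march continues at constant load until either

* the centroid passes the gap-throat plane by one cell radius → escaped, or
* the configuration stops changing, or stops gaining ground for 20
  increments → *suspected* trapped.

A suspected trap is confirmed by up to three lightly-damped relaxations
(damping ÷ 16) with the travelling load refreshed between them: a truly
trapped cell stays put, while a slowly creeping cell — or one resting in a
mesh-scale corrugation of the discrete energy landscape — breaks loose and
the march continues.  The damping floor is deliberate: with near-zero
damping, L-BFGS line searches can step *across* energy barriers that a
viscous quasi-static path could never cross, producing spurious escapes at
high pressures (observed as `Pc` non-monotone in the diameter before the
floor was imposed).  Runs that exhaust the increment budget with neither
outcome are flagged unconverged and treated as trapped with a warning.
States approaching element inversion are rejected and retried with
stronger damping; the hyperelastic kernel switches to a stiff quadratic
barrier below J = 0.05 so line searches back away from inversion smoothly.

### Dimensionless formulation

The solver works internally in lengths divided by the cell radius and
stresses divided by `E`.  Consequently the outcome depends only on shape
ratios and on `P0/E`; critical pressure is *exactly* linear in `E` and
exactly invariant under joint geometric rescaling, as it is for the
continuum boundary-value problem.  Tests assert these invariances through
paired runs at scale factors that are exactly representable in binary
floating point (×2); at non-dyadic factors the last-ulp rounding of the
scaled geometry is amplified by the near-threshold dynamics and the
equality holds only approximately.  The probe ladder of the search scales
with `E` (start `P0/E = 0.002`, doubling from there) so that cells
differing only in modulus traverse congruent dimensionless ladders; with
a modulus-independent start, continuation hysteresis — finer or
differently-phased ladders re-equilibrate at different points — was
observed to shift the reported threshold by up to ~17%, swamping the
bisection tolerance.  The E-scaled start carries no information about the
diameter/gap dependence that sweeps are meant to measure.  The same
hysteresis means a brute-force continuation scan agrees with the bisection
only when its step is comparable to the bisection tolerance; a much
coarser ladder re-equilibrates less often and detaches a few percent
earlier.

### Critical-pressure search

`find_critical_pressure` brackets the escape threshold by doubling the
pressure from 1 Pa and then bisects, by *pressure continuation*: every
probe starts from the trapped equilibrium found at the highest lower
pressure, mirroring how an experiment ramps the pump until the cell
detaches.  Continuation makes the classification sharp and monotone along
the search path; independent cold-start runs near the threshold are
chaotic at coarse resolution (trajectory path-dependence in a corrugated
energy landscape) and can disagree within a ±5–10% band.  The start
pressure is deliberately independent of the diameter and gap: seeding the
bracket from the closed-form prediction would imprint the `(a/g)²` answer
onto the measurement whenever searches follow congruent doubling paths.
The search terminates
when the bracket is narrower than 5% of its upper end (configurable), and
reports the lowest pressure observed to escape.  Cells with `a ≤ g` pass
freely and return `Pc = 0` without simulation.  Because the solver is
dimensionless, sweeps cache the dimensionless threshold per (diameter,
gap) shape and reuse it across moduli.

### Known limitations

* The quasi-static frictionless threshold *saturates* at large `a/g`: as
  the cell transits the slot, material exiting the throat releases elastic
  energy that offsets the cost of material entering, so the net barrier
  slope — and hence `Pc` — grows sublinearly once `a/g` exceeds roughly
  2.5.  Sweeps measured here show a local log-slope of ≈ 2.5–2.7 for
  `a/g ≲ 2.1` falling to ≈ 0.5 by `a/g ≈ 3–4`, so a power-law fit over
  the full working range returns an exponent nearer 1 than the calibrated
  quadratic.  A transient explicit-dynamics treatment of the same problem
  (where the entry barrier dominates and no downstream recovery is
  available within the simulated window) yields steeper effective
  exponents; the two model classes answer subtly different questions, and
  the closed-form quadratic relation should be preferred for design use.
* The coarse default meshes inflate the threshold at small `a/g`: the
  faceted sphere must climb over facet-scale corrugations of the discrete
  energy landscape.
* The trapped/escaped decision is operational (budget, patience, and
  confirmation thresholds); near the threshold the declared `Pc` carries
  the bisection tolerance plus a model fuzz of a few percent.
* No fluid–structure coupling: the load magnitude is decoupled from the
  flow solution (the flow module supplies a suggested `P0` only), and
  lubrication between cell and pillar walls is not modelled.

## Carrier flow

The flow module solves steady incompressible flow in the plan view of the
trapping unit, depth-averaged over the channel height `h` by a Brinkman
drag `−12 μ/h² · u` (Hele-Shaw closure; a flag disables it).  The
convective term is retained and handled by Picard iteration with
first-order upwinding — at device Reynolds numbers (≪ 1 on the unit-cell
share of the flow) it converges in a few iterations and contributes at the
percent level or below.

Discretization: staggered (MAC) finite volumes on a graded rectilinear
grid (target spacing gap/10 inside the gap), with pillars entering as
masked solid cells whose faces carry no-slip values.  The continuity
equations are written per unit volume so all rows of the saddle-point
system share a comparable scale; the system is factorized once (SuperLU)
and re-solved per Picard iteration.  Mass is conserved to solver precision
(inlet/outlet flux balance ~1e-12 relative in the benchmarks).

The trapping-unit domain is one unit cell of an infinite pillar row —
from the gap centreline to the mirror plane through the pillar centre,
with symmetry (slip) lateral boundaries — so the entire unit-cell flux
crosses the gap.  The pump's flow rate refers to the full chamber width
(`FlowConditions.channel_width`, default 2 mm); the unit cell sees the
inlet velocity `Q/(width·h)`.  With the defaults, a 6 µm gap at
10 µL/min develops a mean gap pressure difference of ≈ 49 Pa — the same
scale as the critical pressures, which is what makes the two-step coupling
(flow solve → suggested `P0` for the mechanical load) sensible.

Verification oracles: a wide straight channel reproduces the
plane-Poiseuille pressure gradient `12 μ Q/(w h³)` within 5% (the residual
difference is the physical side-wall correction plus discretization); the
pressure drop is proportional to `Q` across 1/5/10 µL/min to well within
2%; and the velocity profile across the gap is parabolic with `R² > 0.99`
(the Brinkman screening length `h/√12 ≈ 14 µm` exceeds the half-gap, so
the cross-gap profile is viscosity-dominated).

## Synthetic cohorts and device design

The cohort generator emulates the measured A549 size distribution: normal
with mean 17.27 µm and SD 2.91 µm.  The untruncated normal is the default
— truncating to the observed ~12–28 µm range would shift the sample mean
by about +0.23 µm away from the measured value — and truncation is opt-in
(renormalized, via `scipy.stats.truncnorm`).  A histogram generator
reproduces the measured population shares per diameter bin
(60/23/13/5% — as printed they total 101% and are renormalized with a
warning); the printed bins are gappy integer ranges, shipped here as
contiguous half-open intervals [12,18), [18,20), [20,23), [23,28).
Generated cohorts carry a constant modulus (430 Pa) by default; what the
generator does *not* emulate: cell-to-cell stiffness variation, non-normal
tails, cell clusters, and blood-cell backgrounds — so routing statistics
derived from it speak to size selectivity only.

Routing sends each cell through the gap arrays in order (gaps strictly
decreasing from inlet to outlet) and captures it at the first array whose
rule fires: `gap ≤ 0.25 · diameter` (the classical quarter-rule, with ties
counting as captures — a measure-zero choice) or, alternatively, predicted
`Pc > operating pressure`.  Cells never captured are reported as escaped
rather than forced into the last array.  The measured bin-to-array
association is shipped as a data fixture, not derived from a rule: no
single threshold fraction reproduces it (the quarter-rule matches the
smaller cells but not the larger ones).

Operating-pressure curves evaluate the power law for a packaged panel of
six tumor cell lines (literature diameters and stiffnesses).  Under the
power law the between-type pressure ratio is gap-independent — e.g.
A549 : MDA-MB-231 is (430·17²)/(206·15.5²) ≈ 2.51 at every gap — so the
curves are best read as absolute differences when choosing a pump setting.

## Benchmark problem sizes

The shipped test-suite and acceptance benchmarks use the desk-scale
configurations: lattice resolution 3–4 for contact sweeps (one critical
pressure in ~20–60 s on one CPU), grids of a few thousand cells for flow
solves (< 1 s each after factorization), 10⁵-cell cohorts for the
statistical checks.
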