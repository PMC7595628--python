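# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the tests do and do not establish.

## Model overview

The simulator couples two components. The fluid is a D3Q19
lattice-Boltzmann solver on a regular periodic grid: BGK collision with a
single relaxation time τ, Guo forcing (the body and coupling forces enter
both the equilibrium velocity, shifted by half a step, and a source term
weighted by 1 − 1/(2τ)), streaming by one-cell shifts, and full-way
bounce-back at solid nodes. Immersed cells are closed triangular meshes
whose points carry mass and obey Newton's equation under velocity Verlet.
The two components exchange momentum only through the dissipative point
friction F = γ(u − v): fluid velocity is interpolated trilinearly at each
mesh point and the opposite force is deposited with the same weights, so
the exchange is exactly antisymmetric node by node.

Assumptions inherited from this model class: the membrane is a
two-dimensional elastic network with no in-plane viscosity or thermal
fluctuations; inner and outer fluid share one viscosity; the no-slip
condition on the membrane is approximated by friction, not enforced
exactly; walls live on the lattice (bounce-back) and, for contact
mechanics, as analytic shapes with signed distances.

## Units and parameters

All quantities are in mutually consistent "lattice units"; the
recommended scaling is micrometres (length), microseconds (time) and
10⁻¹⁵ kg (mass), which puts blood-plasma-like water at kinematic
viscosity ν = 1.5 and density ρ = 1. Defaults that matter:

* `ks = 0.005`, `kb = 0.02`, `kal = 0.007`, `kag = 0.7`, `kv = 0.9` — the
  red-blood-cell-scale elastic coefficients used by the built-in cell
  types. The two global coefficients are deliberately 2–3 orders stiffer
  so surface and volume stay within a fraction of a percent.
* point mass `m = 1.0` per mesh node (configurable per cell type). The
  model literature rarely states it; dynamics at the overdamped scales
  simulated here depend on it only through the stability bound below.
* MD time step `dt = 0.1` in cell-bearing scenarios. The stiffest membrane
  mode (volume modulus at the parameters above, 162-node cell of radius
  3.91) has a period of roughly 7 time units, so dt = 0.1 resolves it ~70×;
  the explicit friction bound γ·dt/m < 1 is enforced with a warning.
* fluid `dt` equals the MD step divided by `lbm_substep_ratio` (default 1).
* τ follows from ν: τ = ν/(c_s² dt) + ½. The channel-validation scenario
  uses ν = 1/6 (τ = 1), where the bounce-back wall sits most accurately
  half a spacing beyond the solid nodes; cell scenarios use the physical
  ν = 1.5 and accept the (stable) larger τ.

## Mesh and the dihedral convention

A mesh is built from `nodes.dat`/`triangles.dat` (whitespace triplets, ids
by line order; `#` comments tolerated; 0- or 1-based triangle indices via
`index_base`). Construction validates a closed orientable 2-manifold
(every edge borders exactly two triangles, each direction traversed once)
and flips the whole mesh if the signed volume is negative, so orientation
is always outward. Relaxed lengths, areas, angles, total surface and
volume are frozen from the (optionally per-axis resized) input geometry.
Per-axis `resize` is applied about the template centroid *before*
freezing, so elasticity is measured relative to the resized shape.

Each interior edge yields one angle quad (A, B, C, D): (A, B) follow the
winding of the first incident triangle in file order, C and D are the
opposite vertices. The dihedral angle is θ = π ∓ φ, where φ is the angle
between the outward triangle normals N_C = (A−C)×(B−C) and
N_D = (B−D)×(A−D), taking π − φ when (C−D)·N_D < 0 (locally convex) and
π + φ otherwise. This gives flat = π, every angle of a regular
tetrahedron arccos(1/3), sharp convex creases → 0 and reflex creases → 2π,
and mirror reflection maps θ ↦ 2π − θ.

The bending force has the standard four-point structure (N_C/|N_C|² and
N_D/|N_D|² weighted by edge-projection factors; the four forces sum to
zero identically). Its overall sign is fixed by requiring it to be the
exact negative gradient of k_b/2 (θ − θ₀)² under the convention above —
verified against central differences in the test suite. With the opposite
sign pairing (a convention one can find in transcriptions of this force
family, where the roles of θ and θ₀ are swapped) the force is
anti-restoring; "Δθ" here always means θ − θ₀ with the gradient sign.

## The combined force pass

Per-angle bookkeeping lets one loop cover all local moduli: each angle
owns its shared edge (angles are constructed per edge, so this is a
bijection), and every triangle is owned by exactly one angle
(`triangle_owner`, first-in-order). Stretching per owned edge, bending per
angle and local area per owned triangle therefore touch each element
exactly once, and the vectorized implementation evaluates exactly those
element sets — the accumulated total is tested to agree with the five
standalone passes to the accumulation-order rounding (≲ 1e-12 relative).
ΔS_cell and ΔV_cell are recomputed from the current geometry each step
(no incremental caching).

A property worth knowing: the volume force is the exact mesh-level
gradient of k_v ΔV²/(2V⁰) (the per-triangle extra terms telescope around
each vertex fan), and bending is an exact gradient by construction.
The two centroid-distributed area forces are force- and torque-free but
*not* exact gradients of the corresponding quadratic area energies; the
energy-conservation audit therefore runs on the stretching + bending +
volume subset (stretching's potential is integrated numerically, since
the neo-Hookean factor has no closed-form antiderivative), where 10⁴
Verlet steps at γ = 0 hold total energy within 1%.

## Coupling and momentum bookkeeping

The friction force is evaluated once per MD step from the current
macroscopic fluid field and the current point velocity, deposited
(negated) into the lattice force accumulator, and then held constant
through the Verlet update; conservative forces get the standard
two-evaluation treatment. Holding the friction force makes the particle
impulse γ(u−v)·dt equal the fluid's deposit exactly, so in a periodic,
boundary-free system total momentum is conserved to rounding (measured
drift ~1e-13 relative over 10³ steps). The coupling velocity is the
half-force-corrected first moment; solid nodes report u = 0.

`suggest_coupling_gamma` returns η · mean edge length (η the dynamic
viscosity) — a Stokes-like per-node drag scale that shrinks for finer
meshes so whole-cell drag stays roughly discretization-independent. It is
a documented heuristic, not a calibration; an explicit γ in the
configuration always takes precedence.

## Interactions

* **Cell–wall**: soft-sphere V = a·d⁻ⁿ below d_cut, applied along the
  analytic outward normal of each boundary shape at each close node. A
  node at non-positive distance raises a penetration error naming the
  node. Rhomboid signed distances require orthogonal edge vectors (boxes
  in arbitrary orientation); non-orthogonal rhomboids still work as fluid
  obstacles via the containment test.
* **Cell–cell**: membrane collision V = a/(1 + e^{nd}) below d_cut,
  bounded by a (a/2 at contact). Node i is pushed along
  −(n_i − n_j)/|n_i − n_j| — against its own outward normal, away from
  the other membrane — and node j oppositely, so the pair satisfies
  Newton's third law. The crossing test declares interpenetration when
  each node sees the other on its inner side ((x_j − x_i)·n_i < 0 and
  (x_i − x_j)·n_j < 0) and then reverses the push so the membranes are
  driven back through each other. This direction-plus-crossing rule is
  this package's definition; trajectories are not expected to match other
  implementations of the same potential bit for bit. Near-parallel
  normals (|n_i − n_j| < 1e-8) fall back to the centre-to-centre line.
* **Self-cell**: the soft-sphere law between non-neighbouring node pairs
  of one mesh, with neighbourhoods excluded up to graph depth 2 (default;
  1–5 allowed). Pair searches use a k-d tree with the cutoff radius; the
  test suite cross-checks against a naive O(N²) loop.

`a` and `d_cut` have no hidden defaults: enabling an interaction requires
stating them.

## Time stepping and periodicity

One step: conservative forces → friction (deposit) → fluid substeps →
position update → conservative forces at the new positions → velocity
update. Cells are kept in the periodic box by *rigid re-wrapping*: when a
centroid leaves the box the whole cell shifts by whole box lengths, which
preserves every edge, area and angle exactly (individual nodes may
protrude slightly past the boundary; the fluid coupling wraps node
positions itself, and pair distances use the minimum-image convention
implied by that wrap). Checkpoints serialize the complete state
(positions, velocities, populations, counters) with a format version;
restoring reproduces the subsequent trajectory bit-identically. There is
no randomness in the integrator — the only RNG is the seeded generator
used for initial placement.

## What the built-in geometry generator does and does not emulate

Cells are generated as subdivided icospheres (optionally resized per axis
into oblate spheroids). This reproduces the node counts, mesh regularity
and size scales of the target application (162- and 642-node meshes,
radii 3.91 and 7.5 μm) but *not* the biconcave discocyte rest shape of a
real red blood cell, whose parametrization is not part of this package.
Consequences: passing tests establish the conservation structure,
convergence and coupling behaviour of the solver, and order-of-magnitude
realistic cell dynamics; they do not validate discocyte-specific
behaviour (tank-treading thresholds, inclination angles) or calibrated
correspondence between (k_s, k_b, k_al) and measured membrane moduli,
which require the stretching-experiment calibration workflow out of scope
here. Randomly seeded suspensions use a centroid-gap rejection sampler —
adequate for dilute setups; dense hematocrits rely on the membrane
collision to resolve residual contacts during startup.

## Numerical choices and degenerate inputs

* Triangle degeneracy: squared normals below 1e-24 × (edge scale)² raise
  an error rather than returning junk; zero-length edges are rejected at
  build time.
* Ties in `min_angle` resolve to the first minimal angle in angle-list
  order (deterministic given file order).
* The membrane-collision exponential is clamped at exp(700) to avoid
  overflow for absurd n·d products (the value is already ~0 there).
* VTK output is legacy ASCII with %.9g floats; observable tables are
  tab-separated with %.15g, so values round-trip.
* Problem sizes in the shipped validation battery were chosen to complete
  in minutes on one core: 162-node cells, lattices of 12³–16³ (24 across
  the validated channel), 10³–10⁴ steps per audit. All scale up linearly
  in nodes and lattice volume.

## Known limitations

* Single fluid viscosity inside and outside cells; no variable-viscosity
  option.
* No parallelism (the reference application parallelizes over MPI; this
  implementation is vectorized single-core numpy).
* Explicit friction coupling restricts γ·dt/m < 1; stiff coupling needs
  smaller steps rather than an implicit solve.
* The area moduli are not exact energy gradients (see above); with
  damping present this is immaterial, but undamped area-dominated
  dynamics will not conserve a simple energy functional.
* Bounce-back walls sit half a spacing off the solid nodes; geometry
  builders must account for that offset (the built-in scenarios do).
* Wall-contact distances are analytic, not lattice-based, so a shape used
  for contacts should also be added to the lattice mask for consistency.
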