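# Methods

This note documents the models, algorithms, numerical choices and known
limitations of rxnet. Units throughout: lengths in Å, energies in a
Hartree-like arbitrary unit, gradients in energy/Å.

## Toy potential-energy surfaces

The package replaces electronic-structure engines with analytic backends
behind a single calculator contract (`compute(structure, required)` →
energy, gradient, Hessian, bond orders, partial charges). The contract —
not the physics — is what the exploration machinery depends on.

### Pairwise Morse backend

For every atom pair at distance r with covalent-radii sum r₀:

    V(r) = D_e (x² − 2x) + h·exp(−((r − r_c)/w)²),   x = exp(−a (r − r₀))

* `well_depth` D_e = 0.17 (default): the separated dissociation energy of
  a bond, since V(r₀) = −D_e and V(∞) = 0.
* `morse_width` a = 1.9 Å⁻¹: gives realistic-looking force constants
  (2D_e a² ≈ 1.2 energy/Å² at the minimum).
* Bond order: BO(r) = exp((r₀ − r)/b) with decay b = 0.25 Å, capped at 3.
  BO(r₀) = 1 by construction; the scan stop thresholds (formed ≥ 0.75,
  broken ≤ 0.15) and the graph-perception threshold (0.5) are all defined
  on this convention and are config-exposed, since no universal bond-order
  convention exists.
* Optional Gaussian barrier (h = 0.04, centre r_c = r₀ + 0.33 Å, width
  w = 0.07 Å with `barrier_params()`; h = 0 by default). A pure Morse
  dissociation is barrierless — its scan profile is monotone and carries no
  transition-state guess — so a surface that exercises the full
  trial pipeline needs a saddle along the dissociation coordinate. The
  barrier parameters were fixed once from the shape of the resulting
  curve: the crest (≈ r₀ + 0.34 Å) must lie beyond the graph-perception
  distance (r₀ + b·ln 2 ≈ r₀ + 0.17 Å) and before the bond-broken stop
  distance (r₀ + b·ln(1/0.15) ≈ r₀ + 0.47 Å), so a cleavage scan records
  an interior energy maximum before it terminates. For H–H this gives a
  minimum at 0.62 Å (−0.17), a saddle at 0.96 Å (−0.0923) and a shallow
  product-complex minimum at 1.06 Å (−0.112). The Gaussian tail at the
  bond minimum is ~1e−10, so the separated dissociation energy still
  equals D_e to ~1e−10.
* `repulsive_only` pairs keep only the D_e x² wall (inert, noble-gas-like
  pairs with no stationary points).
* Partial charges split the total molecular charge over atoms weighted by
  electronegativity. They exist solely so product separation can assign
  integer fragment charges; they carry no physics.

### Müller–Brown backend

The standard four-Gaussian 2D surface, hosted by a single pseudo-atom
("X") whose z coordinate is frozen at zero. Gradients and Hessian entries
involving z vanish. Because the surface pins the particle in space,
rigid-body modes are *not* zero modes, and the backend declares
`has_rigid_modes = False` so the Hessian analysis skips the projection it
applies to molecular backends. The Gaussian exponents are clipped at 60 to
keep far-out probe points finite.

## Newton-trajectory scans

Both scans replace the natural gradient g with a modified g̃ inside the
steepest-descent update R ← R − α_SD·g̃, α_SD = 0.5 Å²/energy.

**Fragment scan (NT1).** The reactive coordinate R_C connects the
geometric centres of the two reactive sites. Single-atom sites have the
R_C-component of their natural gradient zeroed; multi-atom sites have each
member's gradient orthogonalized to R_C. Every site atom then receives the
same artificial gradient of magnitude α_NT1/2 along ∓R_C (attraction by
default). The ½ normalization makes the constrained-pair distance close by
exactly α_SD·α_NT1 per macro cycle on a non-interacting pair, so
|R_C|/(α_SD·α_NT1) estimates the cycles to collision — a deliberately
simple runtime estimate. Default α_NT1 = 0.1 → 0.05 Å of approach per
cycle. Stop: any cross-site distance < 0.9 × covalent-radii sum.

**Pair scan (NT2).** Each constrained atom's natural gradient is projected
onto the orthogonal complement of the span of all pair vectors it belongs
to (orthonormal basis built over sorted pairs). The span projection — as
opposed to one-pass sequential Gram–Schmidt, whose output would depend on
pair order and stay non-orthogonal to earlier vectors — makes the
surviving gradient orthogonal to *every* constrained pair vector and
yields an exactly null vector for atoms in three independent constraints.
Formation pairs then add ±α_NT2·(r₀/r)·û (the r₀/r weight moves distant
pairs faster, favouring concerted arrival); cleavage pairs add the
unweighted ∓α_NT2·û. Default α_NT2 = 0.05 → ~0.05 Å of separation change
per cycle for a symmetric pair. Stop: all formations have BO ≥ 0.75 or
have collided (distance < radii sum), and all cleavages have BO ≤ 0.15.

Between macro steps, optional micro-cycles relax all unconstrained atoms
with BFGS (scipy, identity initial inverse Hessian) to max-gradient 1e−4
or 50 iterations, constrained atoms frozen. The gradient-call budget
(default 400) counts macro evaluations; a trajectory holds one frame per
macro call. Calculator failures terminate the scan with the partial
trajectory kept; trajectories with more than 5 frames are still analyzed.

## Transition-state guess and refinement

Scan energies are passed three times (configurable) through the 5-point
quadratic Savitzky–Golay kernel (−3, 12, 17, 12, −3)/35 with reflection
padding. The guess is the frame of the highest *interior* local maximum of
the smoothed series (ties → earliest); monotone profiles and trajectories
of ≤ 5 frames yield no guess.

Saddle refinement offers two methods sharing the partitioned
rational-function step (maximize along the lowest eigenmode with the RFO
shift λ_p = (λ₁ + √(λ₁² + 4g₁²))/2, minimize along the rest; near-null
modes carry no step; trust radius 0.1 Å default):

* `bofill` — exact finite-difference Hessian at the start, Bofill-mixed
  SR1/PSB updates (φ = (sᵀξ)²/(|s|²|ξ|²)) along the way, periodic exact
  refresh every 20 iterations;
* `ev_following` — exact finite-difference Hessian every iteration.

Convergence requires max |g| < 1e−6 *and* exactly one eigenvalue < −1e−6
of the Hessian after projecting rigid translations/rotations (molecular
backends only). Zero or several negative modes raise a rejection.
Finite-difference Hessians (central differences of analytic gradients,
step 1e−4, symmetrized) are used throughout — exact enough for the toy
surfaces and backend-agnostic.

## IRC and validation

The saddle is displaced ±0.05 Å (0.01 on the stiff 2D surface tests) along
the imaginary mode and each branch relaxed by damped steepest descent:
step −α·g capped at a 0.05 Å trust radius, α halved on energy increase and
grown 1.2× on acceptance. Convergence at max |g| < 1e−5; plain steepest
descent crawls in stiff, ill-conditioned valleys, and at toy curvatures
this threshold keeps endpoint positions accurate to ~1e−7 while staying
inside the step budget (5000). Higher-order integrators would follow the
minimum-energy path more faithfully but are unnecessary for the validation
role the IRC plays here.

Validation compares canonical graph keys: one endpoint equal to the start
complex and one different → new step; both equal → unchanged; neither →
failed (the saddle does not connect the intended reactants).

Product endpoints are split into connected components; component charges
are integer-rounded partial-charge sums, corrected by ±1 on the largest
rounding residuals so the total is conserved exactly; multiplicities
follow the minimal-spin rule (singlet for even electron count, doublet for
odd). Each fragment is relaxed independently with BFGS before storage.

Energy bookkeeping records both conventions: separated
(ΔE‡ = E(T‡) − Σ E(fragment minima), ΔE_rxn analogous) and complexed
(referenced to the IRC endpoint complexes). Negative complexed barriers —
possible when artificial association over-stabilizes an endpoint — are
stored and flagged, not discarded. Paths are stored as natural cubic
splines of energy and coordinates over normalized arc length (≥ 4 frames).

## Graph keys and deduplication

Connectivity is perceived as an edge wherever BO ≥ 0.5. Canonicalization
is iterative neighbourhood colour refinement (1-WL) seeded by element
labels; ambiguous colour classes are resolved by individualization
branching, keeping the lexicographically minimal serialization
(colour-ordered elements + edge list + charge + multiplicity). This is
exact — key equality ⇔ labelled-graph isomorphism — at worst-case
exponential cost that only highly regular graphs approach; molecular
graphs at this scale resolve in milliseconds. Stereodescriptors are
deliberately absent: the toy potentials cannot resolve stereochemistry.

## Exploration loop

Gears run in a fixed order per iteration: compound gear (optimize, perceive,
key, deduplicate new structures), kinetics gear (`enable_all`, or
`barrier_cutoff` admitting compounds reachable from the inputs through
steps whose forward complexed barrier ≤ cutoff; reverse accessibility is
not modeled), step-trial gear (deterministic lexicographic enumeration,
each coordinate tried once per compound (pair), intermolecular
self-reactions off by default), scheduler (stable sort by job-type rank;
geometry optimizations rank above Hessian jobs), reaction gear (aggregate
steps by unordered compound-multiset pairs). Default is one-step mode:
newly found compounds are sorted into the network but not re-used as
reactants (`explore_products` enables feedback). Jobs run in-process and
sequentially, so fixed inputs and configuration give bit-identical
networks; no randomness enters the default pipeline (the only seeded code
path is randomized cone sampling of extra attack directions, off by
default).

## What the toy surfaces do and do not show

Passing tests demonstrate that the machinery — constraint algebra, scan
termination, filter logic, saddle refinement, IRC validation, graph
bookkeeping — behaves exactly as specified on surfaces whose stationary
points are independently computable (closed forms, 1D root finding, dense
grid + Newton oracles). They say nothing about recovery rates on real
chemistry: pairwise-additive potentials have no many-body effects, no
electronic structure, no realistic TS geometries for polyatomic
rearrangements, and make multi-bond concerted steps geometrically trivial
or impossible rather than merely hard. Published recovery statistics
obtained with semiempirical engines over millions of trials are therefore
out of scope here; the combinatorial trial-count analysis, which is
engine-independent, is reproduced exactly.

## Other limitations

Single fixed spin rule (no spin-state tracking or two-state reactivity);
no barrierless-step bookkeeping; no bifurcation handling; elementary steps
are not deduplicated below the reaction level; identity reactions (atom
permutations) are invisible to the graph-key definition of sameness.
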