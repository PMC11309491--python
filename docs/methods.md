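# Model and methods

## The model

`cellalign` simulates N actively moving cells in a square periodic box of
side L.  Each cell i is an ellipse of fixed area with centroid X_i,
orientation α_i ∈ [0, 2π) and aspect ratio r_i = a_i/b_i; in the
non-dimensional units used throughout (lengths scaled by the reference
length √(A/π), times by the overlap-relaxation time Aη/σ, where A is the
cell area, η the substrate friction and σ the overlap-avoidance strength)
every cell has area π, so a = √r and b = 1/√r.

The dynamics are overdamped gradient flows of a per-cell energy with
contributions from friction, self-propulsion, pairwise overlap avoidance
(energy σ × overlap area), shape restoration and junction/actin terms.
Carrying out the energy minimisation turns the overlap-area integrals into
closed-form sums over the boundary crossing points Y_k of each overlapping
pair — the computational heart of the model, since only crossing points
(not areas) are needed at run time:

    dX_i/dt = −Σ_j Σ_k (Y_{2k−1} − Y_{2k})^⊥ + ν e(α_i)
    dα_i/dt = (2r/(r²+1)) Σ_j Σ_k (|X_i − Y_{2k}|² − |X_i − Y_{2k−1}|²)

with e(α) = (cos α, sin α), ⊥ the left-turn map (x, y) ↦ (−y, x), and the
crossing points ordered anticlockwise on cell i and paired so each paired
arc of i lies inside the partner.  ν is the self-propulsion speed relative
to overlap avoidance.

Optional modules (mutually exclusive by default, since the junction
derivation assumes constant aspect ratio):

* **Shape** (`shape_on`): dr/dt = (4r²/(r²+1)) Σ [sin 2θ_{2k−1} − sin 2θ_{2k}]
  + 16γ(1 + r̄r³)/(1 + r²)(1 − r/r̄), where θ_k parameterises the crossing
  points on the cell's own boundary.  γ is the shape-restoring strength and
  r̄ the preferred aspect ratio.
* **Junctions + actin** (`junctions_on`): zero-rest-length springs of
  strength κ between cell endpoints X ± a·e(α) whenever two endpoints are
  closer than λ (deterministic: they exist exactly while in range), plus a
  supracellular actin bending torque of strength μ that drives polar
  alignment across front-to-back junctions and anti-polar alignment across
  front-front/back-back junctions.

### Energy-oracle consistency

The crossing-point sums are gradients of the pairwise overlap area.  In the
non-dimensional units the exact relations are

    translation term = −∇_X (overlap area)
    rotation term    = −(4r/(r²+1)) ∂(overlap area)/∂α
    shape term       = −(16r³/(r²+1)) ∂(overlap area)/∂r  (fixed area)

The test suite verifies all three against central finite differences of a
polygon-clipped overlap area on hundreds of random overlapping pairs
(relative error < 1e-4), together with pairwise force antisymmetry, frame
equivariance and the monotone decay of total overlap area when ν = κ = μ = 0.
The actin torque is likewise the bending-energy gradient: with cable
bending strength m = μ·a/2 and the same rotational mobility,
torque = −(4r/(r²+1)) ∂[m/(4a)|e(α_i) ∓ e(α_j)|²]/∂α_i.

## Geometry

Boundary crossings of an ellipse pair are computed by substituting cell i's
boundary parameterisation into cell j's implicit quadratic.  With
t = tan(θ/2) this is a real quartic; we solve it in closed form (resolvent
cubic, complex arithmetic) and polish every candidate with Newton iteration
directly on the trigonometric residual f(θ), accepting roots with
|f| < 1e-10.  The closed-form solver is cross-checked in the tests against
numpy's companion-matrix root finder on the same polynomials.  Tolerances:
roots closer than 1e-8 in θ merge (tangency); odd point counts drop the
most tangential point (smallest |f′|), reducing 1 → 0 and 3 → 2, so the
contact count is always 0, 2 or 4.

Degenerate configurations:

* **Containment** (one ellipse strictly inside another) yields no boundary
  crossings and hence zero overlap force even though overlap is maximal.
  Equal-area cells — i.e. every pair the simulation can produce — cannot
  strictly contain one another, so this cannot arise in a run; for
  robustness (and for unequal-area geometry uses) the engine still applies
  a fallback velocity of magnitude b_containing to the contained cell along
  the centre-difference direction and counts the event in the run log.
* **Coincident ellipses** raise an error at the geometry API; the engine
  resolves them with a deterministic 1e-6 jitter of position and
  orientation, counted in the run log.  (Two cells can only become
  coincident from a measure-zero initial condition.)

The independent overlap-area oracle clips two area-preserving polygonal
approximations of the boundaries (vertices scaled by √(2π/(n sin(2π/n))) so
the polygon area equals the ellipse area); at 4096 vertices the clipped
area is accurate to ~1e-6 relative.

## Integration and engine

Explicit Euler with dt = 0.01 (configurable), all terms evaluated at the
pre-step state; positions wrap into [0, L), orientations into [0, 2π).
Aspect ratios are clamped to [1, 16]: values below 1 would swap the axes'
roles mid-step, and the upper clamp is a numerical guard (clamp events are
logged; none occur in the standard experiments).  Contacts and junctions
are stateless and recomputed every step.  The broad phase is the O(N²)
minimum-image distance test plus a separating-axis rejection along the
centre line, which is exact and fast at the population sizes used
(N ≤ 125); the library-level `neighbor_candidates` also provides a uniform
spatial grid for larger N, property-tested as a superset of all overlapping
pairs.  The hot loop (quartic intersections + stepping) is numba-compiled;
a pure-Python reference assembly of the same right-hand side is kept in
`overlap_dynamics.base_rhs` and the two are asserted to agree to machine
precision.

Reproducibility: one seeded generator per run; ensemble member k of a sweep
uses seed = base_seed + k; trajectories are bitwise reproducible from
(params, seed).  An optional rotational-noise flag (variance per unit time,
default 0) exists as an extension point and is off in all standard
experiments.

## Observables

* **Alignment**: S = |⟨e^{2iα}⟩|, the standard 2D nematic order parameter
  (the positive eigenvalue gap of the nematic Q-tensor).  "Equilibrated
  alignment" means S averaged over the final 10% of recorded frames of a
  fixed-horizon run — an operational reading of "measured at the dynamic
  equilibrium" that avoids inventing a stopping rule.
* **Packing fraction**: periodic union area of all cells / L², rasterised
  at 1024² (≈1e-3 relative accuracy); bounded by Nπ/L² with equality iff
  no overlaps.
* **Contact statistics**: over a window of t = 10 sampled at 100 time
  points, the number of distinct overlap partners per cell and the
  durations of maximal runs of consecutive in-contact samples.
* **Alignment length scale**: ℓ from fitting exp(−d/ℓ) to the binned
  nematic pair correlation C(d) = ⟨cos 2(α_i − α_j)⟩ (bin width 0.5,
  d ≤ L/2), capped at L.  This and the alignment definition are the
  field-standard choices; reported length scales should be read
  qualitatively.
* **Junction graph**: cells as nodes, junctioned pairs as edges (parallel
  junctions collapse); degree fractions and, across an ensemble, the
  Pearson correlation and least-squares fit of % degree-d cells against
  final alignment.

## Experiment scales

The "paper" presets hold the full-scale reference conditions (N = 125,
L = 20, T = 400–800, intended for 60–80 replicate ensembles).  The default
desk scale used by the standard ensemble sweeps keeps the area density (Nπ/L² ≈ 0.99) and all
non-dimensional parameters while shrinking to N = 50, L = 12.6, T = 200
with 10 replicates per grid value, so a full one-parameter ensemble sweep
runs in a few minutes on one CPU.

### What the reduced scale does and does not preserve

The reduced preset preserves the microscopic physics exactly (same
densities, same equations, same dt) but not the *locations of
ensemble-level optima*.  Measured behaviour of this implementation, for
users calibrating expectations:

* The base-model mean-alignment profile over ν at desk scale peaks near
  ν = 0.5 at T = 200; at full scale and T = 800 the profile shifts back
  towards small ν (ν = 0.2 beats ν = 0.5), because coarsening of nematic
  domains at small ν is slow and a T = 200 horizon truncates it.
* In the junction+actin model the alignment-vs-κ profile is nearly flat
  with strongly bimodal replicates at κ ≥ 2 (chain-dominated runs near 0.8
  vs clump-collapse runs near 0.4), so the argmax of a 10-seed ensemble is
  dominated by seed noise; the alignment-vs-λ profile peaks at λ = 0.4 at
  desk scale, with the catastrophic clumping collapse at λ = 0.8 robustly
  reproduced.  These profile shapes persist at the full scale in this
  implementation and under local (pair-correlation) alignment measures as
  well as the global order parameter.

Users after ensemble-level optima should run the "paper" presets with many
replicates and treat argmax locations over flat, bimodal profiles with
caution.

## Synthetic data

All populations are generated internally: uniform random positions on
[0, L)², uniform random orientations, aspect ratio fixed at the
experiment's r (or r̄).  This matches the study's initial conditions; no
biological data enters.  What passing tests show is therefore internal
consistency of the mechanics and the reproduction of ensemble trends under
these idealised initial conditions — not agreement with any particular
experimental cell population (real fibroblasts have non-elliptical shapes,
division, and orientational noise, all outside this model).

## Known limitations

* Explicit Euler is first-order; dt = 0.01 was chosen to match the original
  study's time step, and the gradient-flow decay test guards against
  instability at the densities used, but stiff parameter extremes (κ or μ
  ≫ 1/dt) would need a smaller step.
* The junction model is deterministic; stochastic formation/breakage and
  side junctions are out of scope.
* Only aspect-ratio deformations at fixed area are modelled; arbitrary
  shapes are not.
* Cell division is not modelled.
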