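# Methods

This note documents the models, algorithms and numerical choices behind
`fdgen`, in the spirit of a package methods appendix: what is computed, under
which assumptions, and where the genuinely open design choices were made.

## Scope and model class

`fdgen` targets the monodomain description of action-potential propagation:
a single-medium reaction–diffusion PDE for the membrane voltage coupled to an
arbitrary system of cell-model ODEs and algebraic equations, solved with
single-step finite-difference schemes on uniform rectilinear grids (1-D to
3-D).  Single-step means every continuous derivative term is replaced
directly by a difference quotient and the state advances one time level per
step; the three bundled schemes are FTCS (explicit), BTCS (fully implicit)
and Crank–Nicolson.  Multi-step schemes (Lax–Wendroff, Gauss–Seidel
relaxation) are out of scope: their iteration-until-convergence structure
does not fit the declarative replacement pattern.  Robin (mixed
Dirichlet–Neumann) conditions on a single segment are likewise unsupported;
*mixed* conditions in the sense of different types on different boundary
segments are supported.

## Discretization by replacement

Each model equation is discretized by substitution in a fixed order:
arithmetic variables first, then differential variables, then differential
operators.  Variable replacement attaches the full discrete index tuple
(time level `n`, spatial base indices); distributed parameters (constants
that vary by location, such as a stimulus amplitude defined only at certain
nodes) receive spatial indices only; scalar constants stay bare.  Operator
replacement then consumes each `∂^k/∂dim^k` node: the scheme supplies, per
(order, dimension), a stencil template over the generic symbol `v` whose
index offsets are applied to the already-indexed argument.  Because spatial
operator rules are per dimension, a Laplacian written as a sum of
second-derivative terms discretizes to the sum of per-dimension three-point
stencils in any number of dimensions.  Model variable names are retained
throughout; the scheme's generic symbols never leak into the output.

## Boundary handling

A morphology is a lattice of 0/1 nodes; boundary nodes are background nodes
axis-adjacent to material (diagonal-only neighbours are excluded — the
per-dimension three-point stencil never reads them).  Each (boundary node,
direction) pair gets an integer boundary ID encoding (dimension, side,
condition type) as `dim×4 + side×2 + type`, so boundary CSVs are
self-describing.  Discretization templates are anchored at the material node
adjacent to the ghost:

* **Neumann** (prescribed flux, usually zero): a one-sided first difference,
  `(V[n,j−1] − V[n,j])/Δx = g` on the low side and `(V[n,j] − V[n,j+1])/Δx
  = g` on the high side, emitted at level `n` for explicit schemes, `n+1`
  for BTCS, and both levels for Crank–Nicolson (its stencil reads both).
* **Dirichlet** (prescribed value): value clamps at the material edge node at
  the levels the scheme reads — both `n` and `n+1` for FTCS (the condition
  holds at every time), `n+1` only for BTCS, both for CN.

Ghost values under Dirichlet conditions are deliberately *not* assigned up
front: in 1-D the dependency analysis recovers them from the spare interior
equations (the edge time-update equation is repurposed to compute the ionic
current, and the current equation then defines the ghost — the "arrow
reversal").  Where that leaves a ghost unknown without any defining equation
(BTCS needs the new-level ghosts; 2-D corners have two ghosts but only one
spare equation), the pipeline assigns the declared boundary value to exactly
the unmatched ghost unknowns and re-runs the analysis once.  This
ghost-completion pass reproduces the expected 1-D equation sets exactly
(11 equations under Neumann, 13 under Dirichlet, and the BTCS set with its
four new-level boundary/ghost assignments) while making higher-dimensional
Dirichlet problems structurally solvable.  The initial arrays are made
consistent with Dirichlet clamps so that probed boundary values hold from
step 0.

An interior stimulus electrode is modelled the same way: a *clamp*
declaration replaces the voltage time-update equation at one node with a
constant assignment at level `n+1` and pins the initial value.

## Dependency analysis

Unknown classification: arithmetic variables at level `n` and differential
variables at level `n+1` are always unknown; a level-`n` differential value
is known if it is a material node with a declared initial condition, unless
the node is Dirichlet-clamped (the boundary equations then own its value at
every level); ghost (background) values are unknown whenever referenced;
constants, distributed parameters and simulation parameters are known.

Solvability requires a perfect matching of the bipartite graph between
unknown occurrences and equation instances.  Two algorithms are selectable:
a hand-written Ford–Fulkerson augmenting-path search (default) and
Hopcroft–Karp via networkx; both always return matchings of maximum — hence
equal — cardinality, a property the tests verify against exhaustive search.
The Ford–Fulkerson route is seeded with the left-hand-side rule: an equation
whose LHS is a lone unknown is pre-matched to it, which keeps the generated
arrangement in the conventional "unknown on the left" form; seeding is then
extended to maximum by augmentation, so it never costs cardinality.  An
imperfect matching raises an unsolvable-system error listing the unmatched
unknowns and equations (after the one ghost-completion attempt described
above).

The matching induces a directed graph (the matched unknown of equation A
feeding equation B draws A→B); strongly connected components are found with
the standard Tarjan-style algorithm (networkx) and the condensation is
ordered topologically.  Nontrivial components — simultaneous equations —
arise exactly when the model contains algebraic loops or an implicit scheme
couples the new time level.  The topological order ranks components by
longest-path depth from the sources (every edge strictly increases depth, so
this is a valid topological order) with ties broken by (equation template,
instance index).  The layering is what lets loop reconstruction recover one
loop per template per wave instead of interleaved singletons; the exact
arrow set and order may differ from other valid choices, so tests assert
validity, counts and component structure rather than one specific order.

## Code generation

Loop reconstruction merges maximal runs of instances that share one
relativized template (identical equation structure and matched-unknown
offset after expressing all coordinates relative to the instance node) over
consecutive nodes, first along x, then across rows/planes into nested loops.
Each equation is rearranged symbolically (sympy) so its matched unknown
stands alone on the left; the rearrangement is cached per template, so a
loop over thousands of nodes costs one symbolic solve.  If no closed-form
rearrangement exists (e.g. a nonlinear self-referential algebraic equation),
the affected instances fall back to Newton iterations.

Simultaneous blocks emit a dense Newton iteration: residuals `F_i = lhs_i −
rhs_i`, Jacobian entries as symbolic partial derivatives, initial guess from
the previous time level (or the previous step's value for arithmetic
unknowns), absolute residual tolerance 1e−10, at most 50 iterations,
divergence aborting with the step index.  A structurally singular Jacobian
(a residual independent of every unknown in its block) is a generation-time
error.  The linear solve inside Newton is Gaussian elimination with partial
pivoting, emitted into the program so the generated source stays
self-contained; dense algebra is acceptable at the desk scales this
generator targets.

Programs are emitted for two targets.  The host target is a single
self-contained Python file exposing `simulate(steps, probes, record_every)`;
two time levels are stored with swap semantics (single-step schemes read
nothing older), probes record time series with NaN surfacing, and repeated
runs are bit-identical.  The C99 target mirrors the same block structure
with flat arrays and covers explicit schemes; implicit (Newton) blocks emit
in the host target only.

## Stability

For explicit schemes the pipeline checks the diffusion CFL criterion
`Δt ≤ (Δx)²/(2·d·D)` (`d` = space dimension) and warns — never aborts — on
violation.  The first-power form `Δx/(2·d·D)` that sometimes appears in
print is dimensionally inconsistent for a diffusion operator; the warning
message quotes both forms for traceability.  The bound is inclusive, and
`D = 0` or an implicit scheme always passes.

## Bundled studies and their conditions

* **Worked example**: the three-equation membrane model (`dV/dt = −I`,
  `I = J + D ∂²V/∂x²`, `J = C` for `0 ≤ t ≤ 10`) on a line of three material
  nodes padded by two background nodes; stimulus amplitude `C` supplied only
  at the first material node; Dirichlet values `a`, `b` as named constants.
* **Cell-to-cell coupling**: the dimensionless FitzHugh–Nagumo model
  (`∂V/∂t = V − V³/3 − W + J + D∇²V`, `∂W/∂t = ϵ(V + β − γW)` with ϵ = 0.03,
  β = 1.2, γ = 0.3), FTCS with Δt = 0.001, Δx = 1 (grid units) and D = 200,
  which satisfies the 2-D stability bound 1/(2·2·200) = 0.00125.  Cells start
  at the resting fixed point — the real root of `V³ + 7V + 12 = 0`
  (≈ −1.3572), obtained by eliminating W between the nullclines — with
  W = (V+β)/γ.  A subthreshold stimulus is a Dirichlet-style clamp
  `V = −1.0` at the centre node; the Dirichlet boundary variant holds the
  tissue edge at −1.7.  The decay curve samples every diagonal node from the
  centre to a corner (even indices are the measurement interval points, odd
  indices the midpoints) and reports `(V_max − V)/(V_max − V_min)` over the
  probed set.
* **Problem sizes**: the packaged coupling study runs a 25 × 25 tissue for
  10,000 steps (t = 10, several diffusion times at D = 200) — large enough
  for a converged monotone decay profile while keeping a full pipeline run in
  seconds; larger meshes are available through the `--side` option.  The
  single-cell relaxation study runs 250,000 steps (t = 250, about ten times
  the slow recovery time constant 1/|λ_slow| ≈ 21) so the fixed point is
  reached well within the 1e−3 assertion.

## What the synthetic meshes do and do not capture

The generators produce padded lines, squares and boxes of uniform material —
the geometry used throughout the validation studies.  They exercise every
boundary direction, corner handling and distributed-parameter placement, but
not irregular tissue outlines, holes, or anisotropic/heterogeneous diffusion
(D is a scalar constant).  Passing tests therefore demonstrate correctness of
the generation machinery on regular geometries, not fidelity to any imaging-
derived heart morphology; the CSV geometry interface accepts arbitrary 0/1
lattices, but only rectangular ones are covered by tests.

## Known limitations

* All instances are generated eagerly, one per node — generality over
  memory; very large meshes (10⁵+ equations) are better served by purpose-
  built solvers.
* The Crank–Nicolson implicit system is solved as one dense Newton block per
  connected component; no sparse or banded exploitation.
* Units are carried as opaque strings and never checked or converted.
* The compact model dialect is this package's own (line-oriented) stand-in
  for XML model-exchange formats; no CellML/MathML ingestion.
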