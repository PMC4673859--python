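# Methods

This note records the model, the numerical choices, and the reasoning behind
the parameters that ship as defaults. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Geometry and propagation

A mesh is a list of triangular panels, each carrying an orthonormal tangent
frame: origin at the first listed vertex, first axis along `v2 − v1`, normal
`cross(v2−v1, v3−v1)` normalised. Fixing this convention (rather than leaving
it to floating-point accident) makes trajectories reproducible across
machines for a given seed. Molecule positions are stored as (panel, 2-D local
coordinates); 3-D coordinates are derived, never primary, so a molecule can
never drift off the surface.

Edges are matched into adjacencies when their endpoints coincide within a
tolerance (default 1 nm; vertices are merged with a KD-tree union). An edge
owned by more than two panels is an error; an unmatched edge is a reflective
boundary.

A displacement is propagated as straight in-plane motion. On reaching a
shared edge the residual displacement is decomposed into components along the
edge and along the in-plane edge normal and re-assembled in the neighbour's
frame (geodesic unfolding). This is an isometry, so path length is conserved
exactly — verified against two independent oracles: billiard folding on a
flat square (crossing + wall reflections, 10⁴ random steps, agreement ≤
2·10⁻¹⁵ µm) and rotation-about-the-edge for a genuinely folded mesh. On a
boundary edge the residual is reflected specularly. Exit exactly through a
vertex is broken toward the lower-indexed edge; a step undergoing more than
`max_crossings` (default 1000) edge events aborts the run — that signals a
timestep too large for the mesh, which should be fixed, not silently
truncated.

The kernel is written over flat arrays and JIT-compiled with numba when
available; the pure-Python path computes the identical floating-point
sequence.

## Diffusion

The diffusion table maps (species, state) → D with optional per-surface
overrides; lookup is override-first, default otherwise. Storage grows as
(species·states) × surfaces only where exceptions exist. A molecule's step
uses the D of the surface it occupies at the *start* of the step; a crossing
molecule adopts the new coefficient from the next step on. No drift
correction is applied. This Itô-like choice is deliberate: it makes slow
surfaces accumulate molecules (stationary density ∝ 1/D across a sharp
interface), which is the trapping behaviour the simulator exists to study.
The independent 1-D two-zone oracle in `analysis` implements the same step
rule with none of the mesh machinery; at D ratio 100 the 2-D simulator and
the oracle agree on the steady occupancy ratio to well within 10% (the
acceptance suite's check), both near ≈ 90 — below the naive 1/D value of 100
because each interface carries a boundary layer about one rms step wide.

One global PCG64 generator drives a run, consumed in a fixed phase order and,
within each phase, in ascending molecule id. Diffusion draws one
standard-normal pair per live molecule and scales by per-molecule
sqrt(2·D·Δt), so runs whose overrides equal the defaults are bit-identical to
runs without overrides — the reduction-to-uniform check in the acceptance
suite.

## Reaction parameter calibration

Bimolecular channels react any pair within σ_b at step end. σ_b is calibrated
in reduced units of the rms mutual step s = sqrt(2·D_mutual·Δt): the reduced
radius depends only on κ = k/(2·D_mutual). The effective reduced rate of a
candidate radius ρ is the steady-state absorbed flux of a deterministic
radial propagation: number density on a radial grid, one step = convolution
with the exact 2-D Gaussian radial kernel T(r|r′) = r·e^{−(r−r′)²/2}·I₀(rr′)
(computed with the scaled Bessel `ive` for stability), absorption inside ρ,
bulk density held in a reservoir band near the outer cutoff (r_max = 16,
reservoir width 3, in units of s). The steady state is obtained by one dense
linear solve rather than iteration. Because the absorbed density is
discontinuous at ρ, the quadrature grid is split there with a duplicated
node; without the split the trapezoid rule converges only first-order and
overestimates small radii by several percent. σ_b(κ) is then found by
Brent's method; results are cached per κ. A steady-state Monte-Carlo box
(500+500 particles, concentrations held fixed by re-injection) recovers the
requested k to within a few percent across the reaction-limited and
diffusion-influenced regimes.

In two dimensions the diffusion-limited rate is bounded, so a requested k can
be unachievable at a given (D, Δt). `binding_radius_from_rate` raises and
reports the achievable maximum; table construction instead clamps to that
maximum with a warning. The clamp is not a workaround but the model's
behaviour for nearly frozen reactants: the effective on-rate collapses with
D, which is what produces the degradation arm of the scaffold-binding sweep.

For reversible reactions, σ_u is the release separation whose probability of
re-entering σ_b before escaping beyond r_max equals p_gem (default 0.2). The
capture probability as a function of start radius is the solution of the
discrete backward equation on the same grid (one dense solve, then
interpolation). Note the escape cutoff is part of the definition: a 2-D walk
is recurrent, so without a cutoff every pair would eventually recombine. When
p_gem exceeds the capture probability at contact (tiny σ_b relative to s),
products are released at contact — the closest realisable value. Monte-Carlo
release-recapture experiments agree with the requested p_gem within three
standard errors.

Cross-surface pairs (reactants on different surfaces near an edge) use
D_mutual = D_A(surface_A) + D_B(surface_B), i.e. each molecule's actual
mobility. Candidate pairs come from a KD-tree on 3-D positions, are processed
in ascending separation (ties by id), and each molecule reacts at most once
per step. Single products are placed at the pair midpoint, projected onto the
first reactant's panel and clamped into it.

## Engine

Each step executes: (1) zeroth-order creations, (2) first-order conversions
(competing channels share one exponential clock; the channel is chosen
proportionally to rate), (3) diffusion in ascending-id order, (4) bimolecular
reactions in declaration order, (5) observers every `output_interval` steps.
Molecules created in phases 1–2 diffuse in phase 3 of the same step. Time is
`t₀ + n·Δt` by multiplication. Species listed in `confine` treat shared edges
as reflective, which is how "this species may not change surfaces" is
expressed without extra geometry.

## Scenario defaults and what they emulate

**Two-triangle plane** — a 1 µm² square split along its diagonal into `fast`
and `slow` surfaces, D_fast = 0.45 µm² s⁻¹ (a typical extrasynaptic receptor
coefficient) and D_slow = D_fast/100 by default, Δt = 1 ms. Free-diffusion
checks enlarge the square to 400 µm so that wall reflections do not bias the
MSD during a 10 s run (on a 60 µm square ~25% of uniformly placed particles
feel a wall within 10 s and depress the fitted slope by ~2%).

**PIP2/PI3K** — 3 kinases and 500 PIP2 per triangle; PIP2 + PI3K → PIP3 +
PI3K. The catalytic rate constant is not pinned by any printed source, so it
is a named parameter; its default k = 0.01 µm² s⁻¹ with D_fast = 0.01,
D_slow = 10⁻⁴ µm² s⁻¹ and immobile kinase was chosen by rate arithmetic
before any simulation: it keeps the fast triangle reaction-limited (k well
below its 2-D ceiling, initial production ≈ k·c·n_kinase ≈ 30 s⁻¹, so the
500-molecule pool lasts ~25 s) while putting the slow triangle above its
ceiling (≈ 3.6·10⁻³ µm² s⁻¹), the regime in which the fast surface visibly
out-produces the slow one. Kinases are always confined; with crossing
disabled the phosphoinositides are too. The scientific assertions about this
scenario are orderings, never values of k.

**Spine** — a spherical head of radius 0.5 µm, open neck at polar angle 150°,
PSD cap at 35° (≈ 7% of head area; the cap angle was chosen for roughly a
tenth), triangulated into 266 panels (10 latitude rings × 14 segments); 66
AMPAR start uniformly on the ESM at D_ESM = 0.45 µm² s⁻¹, Δt = 1 ms (2 ms in
the sweep runs; rms step 0.04 µm, well below panel size). With scaffolds, 132
immobile scaffold molecules sit uniformly in the PSD and bind AMPAR with
default k_on = 0.02 µm² s⁻¹, k_off = 0.01 s⁻¹, p_gem = 0.2 — again named
parameters with order-of-magnitude defaults (binding fast once a receptor
dwells in the PSD, unbinding slow on the run timescale), with only trends
asserted.

What the generators do *not* emulate: real spine geometries (the head is a
parametric sphere cap), receptor exocytosis and turnover, interactions with
cytoskeletal obstacles, and any activity dependence. Passing tests therefore
demonstrate the simulator's internal correctness and the qualitative physics
of diffusive trapping, not quantitative agreement with any particular
synapse.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale defaults: MSD law with 1000 particles
× 10 s; anomalous exponent from 20 particles × 100 s (α ≈ 0.7 on the
second-decade lag window); occupancy with 1000 molecules × 80 s against a
6000-walker, 80 000-step oracle; first-order decay with 10⁴ molecules;
rate-recovery Monte-Carlo with 500+500 pairs × 4000 steps; PIP orderings as
5-seed averages of 15 s runs; enrichment sweep as 3–5-seed averages of 15 s
runs across six decades of D_PSD; scaffold binding times as 3-seed averages
capped at 40 s. MSD fit windows: the α fit uses the second decade of sampled
lags; linear-slope fits use the same window (through-origin least squares).

## Known limitations

* The per-step mid-crossing rule (whole step at the start surface's D) is a
  first-order discretisation; sub-step coefficient switching is not modelled.
* 2-D rate constants are scale-dependent (logarithmically); the calibration's
  outer reservoir at 16 rms steps is a convention, and recovered rates in a
  box of very different particle spacing can differ by several percent.
* Unbinding radii are defined relative to the escape cutoff (see above).
* The pair search is exact all-pairs/KD-tree; no cell-list optimisation is
  included, which bounds practical populations to ~10⁴–10⁵ molecules.
* Surfaces are piecewise flat; curvature enters only through the mesh.
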