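# surfdiff

Single-particle stochastic reaction–diffusion simulation on triangulated
membrane surfaces, with **surface-dependent diffusion coefficients**.

## The problem

Biological membranes are not homogeneous. Microdomains such as the
postsynaptic density (PSD) of dendritic spines slow the lateral diffusion of
receptors like AMPAR, trapping and concentrating them — a mechanism directly
relevant to synaptic strength and long-term potentiation. Most single-particle
simulators model a membrane domain either by adding boundary fences around it
or by switching a molecule's species when it enters, which multiplies species
and reaction definitions combinatorially.

`surfdiff` instead makes the diffusion coefficient a property of *where a
molecule is*: D is looked up per `(species, state, surface)` — a default per
species plus per-surface exceptions — and every reaction parameter derived
from D (binding radius, unbinding radius) is computed per surface as well. One
species, one reaction definition, any number of diffusive environments.

## The model

* A membrane is a set of named **surfaces**, each a collection of triangular
  panels in 3-D with shared-edge adjacency. Unmatched edges are reflective.
* Each timestep Δt, a molecule takes a tangent-plane Brownian step with
  components drawn from N(0, 2·D·Δt), where D is the coefficient of the
  surface it starts the step on. Steps that leave a panel continue across
  shared edges by geodesic unfolding (rotation about the edge, exactly
  length-preserving) and reflect specularly off boundary edges. This is an
  Itô-type discretisation with no drift correction: molecules accumulate on
  slow surfaces, with steady-state density ratio ≈ D_fast/D_slow.
* Bimolecular reactions fire when two reactants come within a **binding
  radius** σ_b, calibrated by deterministic radial propagation of the pair
  distribution (2-D Gaussian step kernel, absorption inside σ_b, outer
  reservoir) so the well-mixed rate reproduces a requested macroscopic
  k (µm² s⁻¹) at the given D and Δt. Reversible reactions place products an
  **unbinding radius** σ_u apart, calibrated to a geminate-recombination
  probability p_gem with the same machinery. Because D enters the
  calibration, σ_b and σ_u are per-surface quantities.
* First-order channels fire with probability 1 − exp(−k·Δt) per step;
  zeroth-order channels create Poisson numbers of molecules per surface.

Everything is driven either from Python or from a plain-text configuration
dialect whose key statement is

```
surface_difc <surface> <species>[(state)] <D>
```

used *in addition to* the usual `difc <species> <D>` default. Units are µm,
s, µm² s⁻¹ throughout.

## Worked example

Emit the heterogeneous two-triangle plane (a 1 µm² square split along its
diagonal into a "fast" and a 100× slower "slow" surface), run it, and analyse
the trajectories:

```
$ surfdiff scenario two_triangle -p n_molecules=20 -p time_stop=100 -o plane.txt
$ surfdiff run plane.txt --seed 5 --out-dir out
completed 100000 steps to t=100 s; 20 molecules remain
$ surfdiff msd out/traj.tsv | head -4
# particles   20
# slope       0.0137409
# alpha       0.685317
lag   msd
```

The fitted anomalous exponent α ≈ 0.69 < 1: although every molecule obeys
plain Brownian motion locally, the hundredfold diffusion contrast between the
two triangles makes the ensemble mean square displacement sublinear —
emergent subdiffusion, the behaviour observed for crowded biological
membranes. On a homogeneous control far from any wall (`-p D_slow=0.45
-p side=400 -p n_molecules=1000 -p time_stop=10 -p start_surface=split`,
run with `--seed 11`) the same analysis recovers free planar diffusion:
slope 1.79272 µm² s⁻¹ ≈ 4D = 1.8, α = 0.997.

The other built-in scenarios:

* `surfdiff scenario pip` — phosphorylation of PIP2 by membrane-anchored
  PI3K (3 kinases + 500 PIP2 per triangle). Without crossing, the fast
  triangle produces PIP3 ~20× faster than the slow one; with crossing
  enabled, substrate trapping on the slow triangle raises its PIP3 output
  several-fold above its own no-crossing level.
* `surfdiff scenario spine` — a spherical spine head (r = 0.5 µm) whose PSD
  cap is ~10% of the area; 66 AMPAR at D_ESM = 0.45 µm² s⁻¹. Sweeping the PSD
  coefficient from 0.45 down to 0.45·10⁻⁵ µm² s⁻¹ raises steady PSD
  enrichment monotonically from the area fraction (~0.07) to ~1.0. With
  `-p with_scaffold=true`, 132 immobile scaffold molecules bind AMPAR
  reversibly; the time to 90% bound improves from ~7 s to ~3 s as the PSD
  slows tenfold-stepwise, then collapses (>40 s) when the PSD is nearly
  frozen and receptors can no longer reach free scaffold — slower diffusion
  helps trapping only up to a point.

`surfdiff enrich out/counts.tsv --species AMPAR --surface psd --include
AMPAR_Scaffold` prints the PSD occupancy time course used above.

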