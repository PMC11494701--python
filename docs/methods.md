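# Methods

## Reaction model

Each node *i* of a network is a sigma-factor perceptron with species Sᵢ (free
sigma), Aᵢ (free antisigma), and Cᵢ (sigma–polymerase complex), sharing one
pool of core RNA polymerase C with total concentration c^tot.  The reactions,
all mass action, are

    sources → Sᵢ            rate uᵢ                (weighted sigma production)
    sources → Aᵢ            rate vᵢ                (weighted antisigma production)
    Sᵢ + Aᵢ → ∅             rate constant γ₁ᵢ      (irreversible sequestration)
    Sᵢ → ∅,  Aᵢ → ∅         rate constant δᵢ       (degradation)
    Sᵢ + C  → Cᵢ            rate constant γ₂ᵢ      (polymerase capture)
    Cᵢ → Sᵢ + C             rate constant δᵢ       (complex turnover)

Units are μM and hours throughout.  Production rates uᵢ, vᵢ are signed-weight
sums: positive weights feed the sigma, negative weights the antisigma.
Sources are external inputs (layer 1), a constant 1 μM virtual input
(biases and constitutive competitor production), or upstream complexes
(deeper layers), whose contribution is `gain · w · c̄_source` with gain
1 h⁻¹μM⁻¹·μM by default (`NetworkSpec.gain`, and `drive="occupancy"` switches
the source value to c̄/c^tot).

**Complex turnover returns both partners.**  The pool
c_free + Σᵢ cᵢ is then conserved *identically* — the conservation check is an
algebraic identity of the right-hand side, not an integration property — and
the only sigma sink is degradation from the free pool.  Two consequences
define the model's character:

* the free sigma of a node is decoupled from the pool: s̄ᵢ solves the
  sequestration quadratic γ₁s̄² + (δ − γ₁(u−v)/δ)s̄ − u = 0 alone, so adding
  or resizing the polymerase pool never shifts a node's threshold;
* the normalized single-node output c̄ⁿ = Γs̄/(1 + Γs̄), Γ = γ₂/δ, is exactly
  independent of c^tot, which is what makes the saturated-ReLU activation an
  amplitude-scaled, pattern-invariant family as the pool varies.

The alternative turnover choice (degrade the sigma inside the complex,
return only the polymerase) couples s̄ to c^tot and destroys that
invariance; it is not implemented.

Antisigma binds only free sigma, never the complex.  Binding is irreversible;
the complex-turnover step is formally identical to a reversible unbinding
with off-rate δ, which is why steady states coincide with the
reversible-binding treatment.

**Coupled input–output mode** models inputs expressed by the host machinery:
a housekeeping sigma held at a fixed concentration s_c (default 1 μM, no
dynamics of its own) captures polymerase into complexes C_S and C_A (forward
γ₂, turnover δ), and every externally-driven production term is multiplied by
the corresponding housekeeping complex concentration.  The pool conservation
extends over C_S and C_A.  With s_c = 0 nothing is transcribed and the
network stays at zero.

## Steady-state solvers

Two independent routes are implemented and cross-checked (the dual-route
agreement is itself a test):

1. **Integration** (`integrate_to_steady_state`): LSODA from the default
   initial condition (no proteins, pool fully free), rtol 1e-10 / atol 1e-12,
   in doubling time chunks until ‖RHS‖∞ < 1e-9 μM/h (configurable), horizon
   10⁴ h.  Non-convergence flags the result rather than raising.
2. **Exact algebra** (`solve_resource_fixed_point`): for a given free pool
   value c_free, every node's s̄ follows in closed form layer by layer (the
   quadratic above, evaluated on the numerically stable branch), with
   c̄ᵢ = Γᵢ s̄ᵢ c_free.  The scalar pool balance
   g(c_free) = c_free + Σ c̄ᵢ(c_free) − c^tot is strictly increasing on
   [0, c^tot], so the steady state is the unique bracketed root, found by
   Brent's method to machine precision.  A damped fixed-point iteration was
   considered and rejected: the bracketed scalar root is exact, faster, and
   cannot diverge.

On 100 seeded random networks (≤ 4 nodes, bimolecular rates log-uniform in
[0.1, 1000] μM⁻¹h⁻¹) the two routes agree to 1e-6 relative / 1e-9 absolute.

## Parameters and presets

Shared defaults follow the study conditions: δ = 1 h⁻¹, γ₂ = 10 μM⁻¹h⁻¹,
inputs on [0, 1] μM, c^tot in [0, 1] μM.  γ₁ is the regime dial
(ξ = δ²/(γ₁·max production flux); the printed form of ξ was not available, so
this operational nondimensionalization — degradation² over sequestration ×
operating flux — is used; it reproduces every stated regime limit).  The
activation-function presets (`fig2_*`) therefore require γ₁ explicitly; the
documented sweep values are {1, 10, 100, 1000} μM⁻¹h⁻¹.

Preset weights (h⁻¹; sign = sigma/antisigma target):

* `fig3_node` / `fig3_competition`: w = [+1, −1]; competitor production
  (α₂, β₂) = (0.5, 0.5) μM h⁻¹ by default.
* `fig4a_two_node`: node1 (+1 bias, +1·x₁, −1·x₂), node2 (−0.5, +1, +1).
  The tabulated sign placement for this network is internally inconsistent in
  the source table; the signs here follow the described behaviour (node 1
  peaks at (1, 0) in isolation, node 2 at (1, 1)).
* `fig4e_bandstop`: node1 (−1.2, +1, +1), node2 (+0.7, −1, −1),
  node3 (−0.15, +4·c̄₁, +4·c̄₂); c^tot = 0.2 μM.
* `fig4h_bandpass`: node1 (+0.4, −0.5, −0.5), node2 (−0.8, +1.5, −0.5),
  node3 (−0.8, −0.5, +1.5), node4 (+0.3, −1, −1, −1); c^tot = 0.5 μM.

Where a figure's c^tot is not tabulated, 0.5 μM (mid-range) is used.  For the
band-pass network this choice is also functional: the output node's 0.3 μM/h
constitutive bias must be overcome by the summed layer-1 complexes, and
Σc̄ ≤ c^tot, so the design cannot band-pass at all below c^tot ≈ 0.4 μM.
Both band networks default to γ₁ = 1000 (r = 0.01).

## Maps, boundaries, comparisons

Response maps evaluate every node on a uniform lattice (default 51×51 over
[0, 1]²) with the algebraic solver.  A decision boundary is the region
{value ≥ θ·max} (ties included; 4-connected components via binary labeling);
θ defaults to 0.5.  Overlap between two node maps is the fraction of cells
where both exceed ε (default 0.1) of their own maximum.

`deviation_from_ideal` compares a mechanistic map with the ideal
resource-free ReLU network (same signed weights, exact max(0,·) units, no
kinetics, no pool) and reports three numbers: the max absolute difference of
max-normalized maps; the θ-region mismatch fraction; and a decision-region
mismatch (mechanistic onset region at 5% of max vs the ideal map's positive
support, which is the boundary the reference figures draw).  The conventions
matter: the mechanistic activation saturates while the ideal one is
unbounded, so half-max contours of the two maps measure amplitude as much as
boundary placement.  All boundary-based statements in the tests are explicit
about the convention used.

## What the fixture generator emulates

`generate_random_network(seed, …)` draws valid feed-forward networks (≤ 4
nodes, ≤ 2 layers) with bimolecular rates log-uniform in [0.1, 1000]
μM⁻¹h⁻¹, weights uniform in [0, 2] h⁻¹ with random signs, c^tot uniform in
[0.1, 1] μM, δ = 1 h⁻¹.  It spans the kinetic regimes of the study
(slow/fast sequestration, slow/fast competitive binding) for solver
cross-checks and property tests.  It does not emulate features of real
circuits outside the model: transcription/translation as separate stages,
cell growth and dilution, stochasticity, reversible binding off the
steady-state manifold, or delays — so passing tests certify the mass-action
steady-state model, not wet-lab behaviour.

## Numerical choices and degenerate inputs

* Quiescence criterion ‖RHS‖∞ < 1e-9 μM/h; conservation asserted at 1e-8 on
  integration outputs (observed ≲ 1e-14).
* The sequestration quadratic uses the stable root branch
  (2u/(b + √(b² + 4γ₁u)) for b ≥ 0); u = 0 yields s̄ = 0 exactly.
* Zero maps produce explicitly flagged empty boundaries; zero ideal or zero
  mechanistic maps flag the ideal comparison degenerate.
* Grid ties at exactly θ·max belong to the region (≥).
* All-zero production networks are valid and settle at the all-free-pool
  state.

## Problem sizes

Default test and acceptance runs use 51×51 grids for classifier structure,
21×21 for monotonicity sweeps and limit checks, and 100 random networks for
the dual-solver cross-check; the whole suite completes in well under a
minute on one core.

## Known limitations

* The mechanistic half-max region of the band-stop network deviates from the
  ideal reference by more than the 10% grid-cell budget at r = 0.01
  (43% at θ = 0.5; 12% comparing onset region against ideal support): the
  sequestration knee, of width ~√(u/γ₁) in s̄, offsets the mechanistic onset
  by ~0.05–0.1 μM of summed input at γ₁ = 10³.  The deviation vanishes as
  sequestration speeds up (2.9% at γ₁ = 10⁴, 0 at 10⁵ for the onset metric);
  the corresponding test is left failing at the r = 0.01 study condition
  rather than re-tuned.
* Whole-network normalized maps are only approximately c^tot-invariant
  (exactly invariant for single nodes): layer-2 production scales with
  upstream complex concentrations while biases do not, shifting the onset by
  ~0.01 μM of summed input between c^tot = 0.2 and 0.6 (the dual-region
  structure, component count, and corner coverage are preserved).
* No stochastic, spatial, delay, or growth-coupled effects; no learning.
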