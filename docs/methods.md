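# Methods

## The problem

The chemical master equation (CME) describes the probability u(x,t) that a
reaction network with d species occupies the copy-number state
x ∈ ℕ^d:

    ∂u/∂t = L u,   (L u)(x) = Σ_i [ a_i(x−ν_i) u(x−ν_i) − a_i(x) u(x) ],

where ν_i is the stoichiometric jump of channel i and a_i(x) its
propensity.  Direct solution on a truncated box is exact but the number of
unknowns explodes with dimension (the bistable toggle switch on [0,300]²
already needs a 90601×90601 operator).  In most regimes, however, u is
negligible outside a thin, possibly multi-component region — the
*essential support* {x : u(x) > p_threshold}.  This package solves the CME
by Gaussian radial-basis-function (GBF) collocation on a node set that
tracks that region through time.

## Full-grid reference solver

`rbfcme.fullgrid` assembles L as a sparse matrix over a `LatticeBox` with
a *conserving* truncation: a channel whose target state leaves the box is
switched off at the source, so every column sums to zero and total
probability is conserved on the box.  (The alternative, absorbing
truncation, would make the mass-deviation diagnostics of the adaptive
solver meaningless.)  Transients use `scipy.sparse.linalg.expm_multiply`
(action of the matrix exponential; the dense exponential is never
formed).  Steady states use shift-invert Arnoldi about a point just left
of zero with a bordered direct solve as fallback; because the sparse-LU
fill-in of 3-D boxes beyond ~1.2·10^5 states is prohibitive, larger
problems switch to a relaxation path — repeated application of exp(TL)
with doubling horizons and an ∞-norm residual check.  For metastable
systems the relaxation start must share the symmetry of the target
(slow inter-mode modes make the residual alone an incomplete closeness
certificate); the symmetric systems solved here start from a symmetric
Gaussian, which keeps the antisymmetric slow modes at round-off level.

## GBF collocation

Each node x^i carries an anisotropic Gaussian
φ_i(x) = Π_k exp(−(x_k − x^i_k)²/σ^i_k).  The interpolation matrix
A_ij = φ_j(x^i) is factorized once (dense LU; node counts stay in the low
thousands) and reused by all operator builds.  Coefficient-space
operators:

* shift along axis k:  T̃_k = A⁻¹A₁ with (A₁)_ij = φ_j(x^i − e_k) — the
  nodal values of the shifted interpolant, re-expanded in the basis;
* multiplication by a propensity:  W̃_a = A⁻¹ diag{a(x^i)} A;
* generator:  L̃ = Σ_i (Π_k T̃_k^{ν_ik} − I) W̃_{a_i};
* stepping:  α(t+Δt) = exp(Δt·L̃) α(t) via `expm_multiply`.

In the limit where the nodes enumerate every lattice state and the
Gaussians become sharply peaked, these reduce to the exact lattice
operators; the test suite exploits this on 1-D chains.

**Shape parameter.**  σ^i_k = (c·h)² with h the candidate-grid spacing.
The neighbour overlap is e^(−1/c²); larger c gives lower off-node
interpolation error but a worse condition number of A.  On a spacing-5
grid over the toggle-switch steady state the relative representation
error falls by more than an order of magnitude between c = 0.85 and
c = 1.2 (reaching below 10⁻³) while cond(A) stays below 10³, which
saturates with the node count for fixed c.  The package default is
c = 0.85 — a
conservative choice that behaves well even when features are only a
couple of cells wide (unit-spacing grids); the 2-D production runs use
c = 1.2, where the smooth, well-resolved solution makes the lower floor
worthwhile.  A 1-norm condition estimate is computed on construction and
a hard cap (10¹²) aborts with a diagnostic.

**Positivity and conservation are not guaranteed.**  Collocation neither
preserves positivity between nodes nor conserves the lattice mass of the
interpolant; both are monitored instead of enforced.  In particular, the
restriction of L̃ to a truncated support generally has a dominant
eigenvalue slightly off zero, so the solution decays (support cut through
non-negligible probability) or grows (interpolant tails spilling across
the x_k = 0 boundary, noticeable when the distribution hugs the boundary)
at a slow exponential rate.  Reported comparisons therefore use
mass-renormalized profiles where shape is the question, and the raw mass
is logged at every step.

## Support geometry

All geometry lives on the fixed candidate-centre grid; distances are in
grid-step units.  A point set is regularised into an *alpha-region* — a
lattice approximation of the alpha-hull — by morphological closing with a
Euclidean ball of radius α (default 2 cells, lower bound 1): holes and
gaps narrower than ~2α are filled, clusters farther apart stay disjoint,
and α → ∞ approaches the rasterized convex hull.  The exact
computational-geometry alpha-shape is deliberately not used: the nodes
live on a grid, and closing reproduces the hole-preserving/hole-filling
behaviour that matters here while keeping every operation on the
Cartesian grid.  Near box faces the mask is edge-replicated before the
erosion so the box boundary itself does not erode the region, and the
closing is forced to contain its input.

The signed Euclidean distance field (negative inside) is computed with
exact distance transforms; unions are pointwise minima; inflation by γ is
the γ-sublevel set.  The support at the next time point is predicted by
linear extrapolation of the SDF in time (a first-order discretization of
the level-set transport equation under locally constant boundary speed);
for rigid translations this is exact to one cell in the Hausdorff metric.
Support validation uses the sup-norm of the SDF difference over the union
of both alpha-regions.  Component counting uses face (von Neumann)
connectivity, matching the unit-step reachability of CME jumps.

## The adaptive loop

1. **Initialize**: essential support of u₀ at the threshold (relative to
   max u by default), alpha-region, inflate by γ (default 2 cells), place
   centres on the candidate grid inside the inflated region, interpolate
   u₀.  If the off-node error exceeds the threshold, the grid is refined
   (halved) up to a retry budget.
2. **Bootstrap**: the first step integrates with the prediction equal to
   the current support (no history yet).
3. **Predict–step–validate**: extrapolate the support, rebuild the basis
   on the inflated union of current support and prediction, transfer
   coefficients by evaluating the old interpolant at the new centres
   (conservative at the rim thanks to the γ layer; genuinely new centres
   see the old interpolant's decay toward 0), step with exp(Δt·L̃), then
   compare the essential support of the result against the prediction.
4. **Control**: a step is rejected if the support discrepancy exceeds
   `support_tol` (time step shrinks by `dt_shrink`) or if the incremental
   mass change exceeds `mass_tol` (support cutoff is halved — a larger
   support leaks less).  Each time the *cumulative* deviation from the
   initial mass crosses another multiple of `mass_tol`, the cutoff is
   halved for subsequent steps.  The time step re-expands to `dt_init`
   after acceptance — no growth heuristic, keeping runs reproducible.
   A hard cap on consecutive rejections aborts with diagnostics
   (thresholds cutting through high-probability regions fragment the
   support and are not recoverable by step control; observed for the
   toggle switch at cutoffs ≳ 0.1·max u, where the run also loses mass
   rapidly — exactly the regime the mass monitor exists to flag).
5. **Stationarity**: the run stops early when the mass-normalized profile
   changes slower than `ss_rtol` per unit time (shape-based, so a slow
   uniform decay through the cutoff does not mask convergence).

The interpolant's lattice mass is computed exactly per step from
per-axis 1-D Gaussian sums (the lattice sum factorizes), cached per
basis.  The per-step log records time, degrees of freedom, support mask,
mass, discrepancy and rejection count.

## Worked systems and study sizes

* **Bistable toggle switch** (two mutually repressing genes, Hill
  repression c₁/(c₂+y^β) with c₁ = 3·10³, c₂ = 1.1·10⁴, decay 10⁻³,
  β = 2): modes near (223, 49)/(49, 223) on [0,300]².  The exact steady
  state's inter-mode valley tops out near 0.02·max u, so supports split
  into two components only for cutoffs above that level; production runs use
  grid step 5, c = 1.2, Δt = 2000, t_end = 2·10⁵ with shape-based early
  stopping (the saddle-escape e-folding time is ≈ 7.7·10³, so
  equilibration genuinely needs ~10⁵ time units).
* **Scaled tristable switch**: the three-species generalisation at full
  scale (modes ≈ 270) needs a [0,300]³ box — out of reach of a reference
  solve at test sizes.  The package's scaled study condition reduces
  production tenfold (c_prod = 300 → modes ≈ 29 on [0,60]³) and steepens
  the Hill exponent to 4.  The steepening is essential, not cosmetic: at
  tenth-scale copy numbers the relative noise is ~3× larger and, with
  exponent 2, the symmetric central fixed point (which is linearly stable
  for this propensity family at *any* scale — Jacobian eigenvalues
  −c_deg + b·μ with μ ∈ {2,−1,−1} and b < 0 are all negative) collects
  the probability mass, washing out the corner modes entirely.  Exponent
  4 restores the full-scale topology: a trimodal, permutation-symmetric
  stationary law whose essential support is three-connected across
  cutoffs from 0.01 to 0.5 of the maximum.
* **Osteochondro switch (OCS)**: progenitor/osteogenic/chondrogenic
  regulators with asymmetric Hill propensities; the default parameter set
  is bistable, lowering the progenitor inflection point m_p to 8 makes it
  tristable, and a stimulus z_o > 0 added to the osteogenic production
  numerator biases the fate decision.
* **Self-regulating gene**: a two-component master-equation system (free
  vs repressor-bound DNA) encoded on a doubled lattice so the same
  operator machinery applies.  The h/f coupling terms are implemented in
  the probability-conserving orientation (binding moves mass u_on → u_off
  at fixed protein count, release the reverse), with an additional
  channel off(1) → on(0) at rate k — degradation of the bound repressor
  frees the DNA — and off-state degradation blocked below one protein so
  that u_off(x<1) = 0 exactly.  Binding does not change the protein
  count, and dimer binding does not decrement by two; derived unitless
  parameters X_ad = (g_on+g_off)/2k, X_eq = f/h, ω = f/k are exposed.
  Slow switching (small ω) yields a bimodal protein distribution; the
  peaks fuse as ω grows.

## Gillespie baseline

Direct-method SSA over the same boxes, with per-channel propensities
tabulated once (conserving truncation, so trajectories cannot leave the
box) and a numba-compiled jump loop; a pure-Python loop with the
identical Mersenne-Twister stream backs it for verification.  The
occupancy distribution weights states by waiting time (the ergodic
estimator of the stationary law); raw visit counts are available behind a
flag.  3^d box smoothing uses edge-truncated renormalized windows with a
final mass rescale, so a constant field is unchanged and mass is
preserved exactly.

For the toggle switch, 10⁷-step trajectories switch modes on the order
of ten times, and the l2 distance between occupancy and exact steady
state is governed almost entirely by the mode-dwell imbalance:
err ≈ |2f−1|·‖u_A−u_B‖₂ with f the fraction of time spent at x > y and
u_A, u_B the two single-mode halves of the stationary law.  Values
observed over seeds span ~0.001–0.008 at 10⁷ steps
(`scripts/acceptance.py` recomputes them).

## What the synthetic inputs do and do not emulate

Initial conditions are closed-form lattice Gaussians and the test
fixtures are small birth–death chains (closed-form truncated-Poisson
stationary law), on-grid Gaussians and rigidly translating masks.  These
exercise every code path — multimodal splitting, support transport,
boundary hugging — but they are noiseless, low-dimensional and built from
the same Hill/linear propensity families the solvers target; passing
tests say nothing about misspecified propensities, measurement noise, or
d > 4 state spaces (explicitly out of scope: the dense interpolation
matrix and the full-lattice geometry scale poorly beyond four species).

## Numerical choices

* Tolerances: `expm_multiply` at its default (effectively machine-level)
  accuracy; steady-state residual 10⁻⁸·‖diag‖∞ (10⁻⁷ for the 3-D relax
  path); interpolation round-trip asserted at 10⁻⁸.
* Degenerate inputs: empty supports raise; absorbing SSA states
  terminate the trajectory early and are flagged; zero-propensity
  channels drop out of the sparse assembly.
* Tie-breaks: the essential support uses a strict inequality; component
  counting uses face connectivity; the candidate grid anchors at the box
  lower corner.
* Randomness: every stochastic routine takes an explicit seed; the SSA
  kernel's stream is identical between the numba and Python paths.

## Known limitations

* Collocation can go (slightly) negative between nodes and does not
  conserve mass; both are monitored, not enforced.
* Distributions hugging a lattice boundary inflate the interpolant's
  spill-over across it; the 1-D gene-model runs therefore use the full
  unit-spacing grid, where the exact solver is cheap anyway.
* The relax steady-state path certifies only the residual; for metastable
  systems its answer is trustworthy only from a symmetry-matched start.
* The alpha-region is a grid-morphology approximation of the alpha-hull;
  boundary placement is accurate to about one cell, which bounds the
  accuracy of support validation and extrapolation alike.
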