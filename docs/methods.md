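# Methods

## Tangent-space projection

A cell's measured velocity v_i is replaced by its representation in the local
displacement basis of the k-nearest-neighbor graph: v∥_i = Σ_j φ_ij δ_ij with
δ_ij = x_j − x_i over the neighborhood N(i). The weights minimize

    L(φ_i) = a‖v_i − Σ_j φ_ij δ_ij‖² − b·cos(φ_i, φ_i^corr) + λ‖φ_i‖².

Assumptions: the sampled states cover the manifold densely enough that the
displacement vectors span the local tangent space, and the measured velocity's
tangential component is informative (the projection can remove off-manifold
noise but cannot recover signal that was never measured).

**Solver.** Each cell is an independent small problem. With b = 0 the loss is
quadratic and is solved in closed form (ridge normal equations; ordinary
least squares via `lstsq` when λ = 0, which makes the b=0, λ=0 configuration
exactly the OLS projection onto span(δ)). With b > 0 the bounded cosine term
is added to the convex part and the loss is minimized by L-BFGS-B with the
analytic gradient, initialized at the ridge solution (λ floored at 1e-12 for
the initializer so it is defined when λ = 0). The best of {initializer,
final iterate} is returned, so the reported loss never exceeds the loss at
initialization; hitting the iteration cap raises a warning, never an
exception. Results are independent of the order in which cells are
processed. Cells with an all-zero velocity get φ = 0 directly (the cosine
term is undefined at the origin). Convergence: ftol 1e-6, max 200 iterations.

**Hyperparameters.** a = 1, b = 10, λ = 1 by default. a scales the
magnitude-matching term, b the direction anchor, λ the L2 bound on the
weights (all dimensionless). k = 30 neighbors by default for expression
graphs and k = 8 for spatial-coordinate graphs; union graphs (expression ∪
spatial) are ragged and every per-cell loop tolerates variable neighbor
counts.

**Missing velocities.** Features without a velocity estimate carry NaN in the
`"velocity"` layer. Dimensions that are NaN in v_i are dropped from both v_i
and δ_ij when fitting φ_i; the fitted weights are then applied to the full
displacement basis. Transferring velocities to entirely unmeasured features
(other genes, chromatin peaks, hidden coordinates) is the same operation with
a different target basis — the only assumption is that the manifold seen
through the measured features is locally homeomorphic to the one seen through
the full feature set.

**φ^corr.** The cosine-kernel weights are the raw cosine similarities
cos(v_i, δ_ij), zero where either vector vanishes, with no further
normalization or rescaling before entering the cosine term of the loss. The
comparator `baseline_cosine_projection` normalizes by Σ|φ^corr| and therefore
does not preserve magnitude; it exists only as the benchmark baseline.

**Displacement source.** Displacement bases use the raw state matrix;
optional neighborhood first-moment smoothing applies to the velocity layer
only (`smooth_velocity=True`). Smoothing the states as well would shrink the
basis toward neighborhood centroids and bias the recovered speeds.

**Adaptive step.** For carrying velocities through a (possibly nonlinear)
coordinate map by state extrapolation, the per-cell step is
dt_i = median_j ‖δ_ij‖ / ‖v_i‖, which keeps x_i + v_i dt_i within the local
sampling scale. For a linear map the dt cancels and the result equals v_i Q
identically; cells with zero speed are flagged and emit zero vectors.

## Evaluation scores

* **MacK** (manifold-consistent kinetics): per cell and gene, the fraction of
  neighbors with Δt ≠ 0 whose finite-difference sign sgn(Δx_ij/Δt_ij) matches
  sgn(v_i(g)). sgn(0) is treated as its own symbol so silent genes do not
  inflate the score; neighbors tied in pseudotime are excluded (the finite
  difference is undefined there). The per-gene score is the unweighted mean
  over cells with at least one usable neighbor; with this two-stage
  aggregation the two readings of the formula's leading 1/n (per-cell
  neighbor count vs cell count) coincide.
* **CBC** (cross-boundary correctness): mean over boundary cells of state A
  (cells of A with ≥ 1 neighbor in B) of the mean cosine between the cell's
  velocity and the displacements to its B-neighbors. Computed in the full
  expression space by default; 2-d embeddings distort these geometric
  relationships.
* **Consistency**: mean cosine between a cell's velocity and its neighbors'.
* **Speed**: per-cell L2 norm over a feature subset (e.g. viral genes only).
* **Kinetic rates**: with the β ≡ 1 convention, α = u + du/dt and
  γ = (u − ds/dt)/s per cell and gene; entries with s < 1e-6 are masked.
  du/dt comes from transferring the spliced-space tangent weights to the
  unspliced feature block unless exact derivatives are supplied.

All cosine-based scores are invariant under positive rescaling of the
velocities, and CBC is antisymmetric under v → −v on a fixed boundary set.

## Synthetic data

The generators define the benchmark conditions; all are seed-deterministic.

* **Toggle switch** (2,000 cells by default): mutual inhibition with self
  activation, ẋ = a1 xⁿ/(S1ⁿ+xⁿ) + b1 K1ⁿ/(K1ⁿ+yⁿ) − γ1 x and symmetrically
  for y, simulated by Euler–Maruyama with multiplicative (copy-number-scaled)
  noise on the Hill drift, timescale τ = 1. Rate constants are repo choices:
  a = b = 30, S = 35, K = 25, n = 4, γ = 1, giving stable branches near
  (56, 1)/(1, 56) so the states span a meaningful fraction of the radius-70
  sphere below. Ground-truth velocity at each sampled state is the
  deterministic drift evaluated there. A stochastic-simulation backend over
  an explicit reaction decomposition would concentrate states near the same
  deterministic manifold, which is the property the downstream tests use.
* **Sphere lift**: z = sqrt(max(r² − x² − y², 0)) with r = 70; ż by one-step
  finite difference with dt = 1 (converging to −(xẋ+yẏ)/z as dt → 0). The
  ~0.3% of states that the SDE noise pushes past the rim are clipped to
  z = 0.
* **Noise injection**: isotropic Gaussian per coordinate, or ε·n̂ along the
  radial normal (off-manifold noise) — the regime for the projection
  benchmark; the noise level there is the median ground-truth speed.
* **Variable degradation**: dm/dt = α_m − γ_m m,
  du/dt = (α0 − k_α m) − β u, ds/dt = β u − (γ0 + k_γ m) s from the
  unperturbed steady state (u0 = α0/β, s0 = α0/γ0, m0 = 0). The coupling
  enters through the microRNA level m, matching the stated mechanism. Repo
  fixture defaults: α0 = 10, β = 1, γ0 = 1, k_α = 2, k_γ = 3, α_m = 1,
  γ_m = 0.5, t_max = 10 (guard: k_α·max(m) < α0 keeps transcription
  non-negative). Adaptive Runge–Kutta, rtol 1e-8.
* **Transcription burst**: from u0 = s0 = 0 with constant γ, α jumps
  threefold at t_burst; integrated piecewise so the discontinuity is exact.

What the generators do **not** emulate: count noise and sparsity of real
sequencing data, library-size variation, estimator-specific velocity error
structure, high gene dimensionality, and doublets/ambient contamination.
Passing the benchmarks shows the geometry of the method is correct — off-
manifold noise removal, magnitude preservation, exactness of the basis swap —
not that any particular upstream estimator is accurate on real data.

## Vector field

Γ(x, c) = exp(−w‖x − c‖²) — any constant in the exponent folds into w, which
is exposed directly; the default is the inverse median squared pairwise
distance of the centers. Centers are a seeded uniform subsample
(min(500, n/2) by default). Coefficients solve the normal equations
(KᵀK + λ/2·G)C = KᵀV; λ defaults to 1e-3 of trace(KᵀK)/m, a robust setting
for noisy data that trades a few percent of amplitude for stability — for
noise-free fidelity checks pass a small explicit λ. A singular system with
λ = 0 falls back to the pseudo-inverse with a warning. The Jacobian is
analytic (J(x) = Σ_a Γ_a coef_a ⊗ (−2w(x − c_a))); dose–response curves
integrate the bin-averaged Jacobian element over 20 equal-width bins of the
regulator's range, carry empty bins forward, start from an arbitrary constant
F0 (default 0 — curves are defined up to an additive constant), and log a
warning when within-bin variance is large (stratify cells first in that
case).

## Trends

P-spline: cubic B-splines on 10 interior equally spaced knots, second-
difference penalty on coefficients (constants and linear trends are
unpenalized and reproduced exactly), penalty weight by generalized
cross-validation over a fixed grid 10^{-4..6} unless given explicitly.
Trends are evaluated on 100 equally spaced grid points spanning the observed
axis. Clustering: kNN graph (k = 15) on Euclidean trend distances, Leiden
RB-configuration partition at resolution 0.3, seeded. DTW: classic dynamic
programming with squared local cost and symmetric steps, distance = sqrt of
the accumulated cost (the convention of the standard DTW packages); trends
are min-max normalized to [0, 1] per gene first (constant trends map to
zeros), so the report is invariant to positive rescaling of either modality.
Decoupling cutoff: genes ranked by descending distance; the elbow is the
point of maximum perpendicular distance to the chord of the (axis-normalized)
ranked curve, and genes strictly above the elbow's distance are flagged.
Larger DTW distance = more decoupled; distance is a dissimilarity throughout.

## Numerical conventions and degenerate inputs

* Feature/cell order is authoritative; all cross-references are 0-based
  integer positions.
* kNN ties are broken by ascending cell index (exact for n ≤ 4096 where an
  all-pairs stable sort is used; above that a tree-based search takes over
  and exact ties are vanishingly unlikely).
* Union graphs keep the minimum distance for neighbors present in both
  inputs.
* Cells with empty neighborhoods are flagged, never fatal: projection copies
  the input velocity, transfer emits zeros.
* Degenerate trend axes (all-equal pseudotime) and constant dose-response
  regulators raise errors; a CBC call with no boundary cells warns and
  returns NaN.
* Matrices may arrive scipy-sparse; operations densify through a single
  helper and are agnostic to the storage.

## Problem sizes

The shipped benchmarks use 2,000-cell simulations (toggle switch/sphere),
500–2,000-cell score null models, 400–800-point vector-field fits, and
100-gene trend cohorts — sizes at which every pipeline stage is exact or
well-converged while the full test suite and the acceptance script each run
in about a minute on one CPU.
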