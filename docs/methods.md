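# Methods

This note records the mathematical conventions, numerical choices and known
limitations of the package, at the level of detail a user fitting their own
data (or extending the code) needs.

## Discretization and conventions

A surface is a triangle mesh with a *fixed* combinatorial structure; the
vertex positions are the only unknowns in every solver. Faces are stored
with their smallest vertex index first (a cyclic rotation, so orientation is
preserved) and oriented so `(v_j−v_i)×(v_k−v_i)` is the consistent normal.

First-order quantities live on faces. The edge matrix `dq_f` is the 2×3
row-stacked pair `[e01; e02]`, the pullback metric is `g_f = dq_f dq_fᵀ`,
and every pairing of 2×3 matrices is written `tr(g_f⁻¹ A Bᵀ)`. Under this
convention `tr(g⁻¹ dq dqᵀ) = 2` on every non-degenerate face — a sanity
anchor asserted in the tests. (Writing the differential as the transposed
3×2 Jacobian gives the same scalars with the factors reversed; one
convention is fixed project-wide.)

Zeroth- and second-order quantities live on vertices: `vol_v` is one third
of the incident face areas (so Σ_v vol_v equals the total area exactly),
and the Laplacian is the integrated cotangent operator

    (Δ_q h)_v = Σ_w (cot α_vw + cot β_vw)(h_v − h_w),

with one-sided weights on boundary edges (the treatment of boundaries is a
choice of this package; see "Open choices" below). A
`laplacian`-with-`mass_normalized=True` variant divides by `2 vol_v` for
users who want the pointwise operator. Cotangents are clamped to `|cot| ≤
1e4` and faces with area below `1e−12 ×` (bbox diagonal)² are flagged
degenerate; degenerate faces contribute zero to first-order terms and to
the Laplacian rather than NaN, which keeps energies finite on noisy or
partially collapsed meshes (states the optimizer routinely visits).

### The four-way split

On each face the differential `dh` decomposes into `dh_m + dh_+ + dh_⊥ +
dh_0` (shearing / scaling / bending / parameter rotation), computed from
`dq`, `g⁻¹` and `dh` by closed-form 2×2 algebra. The parts are pairwise
orthogonal under `tr(g⁻¹ · ·ᵀ) vol_f` to round-off, sum to `dh` exactly,
and for `h = q` give `dh_+ = dq` with the other three parts zero (pure
scaling) — all asserted in the tests.

### Metric coefficients

`(a0, a1, b1, c1, d1, a2)`, all dimensionless and ≥ 0, default `(1, 1, 1,
1, 1, 1)`. `a0` controls positional fidelity (and is the only term that
penalizes pure translation of mass), `a1/b1/c1` penalize shearing, scaling
and bending, `d1` the in-plane reparametrization rotation (kept at the same
magnitude as `c1` by default), and `a2` smoothness of the velocity field.
The pure-`a0` (L²) metric is degenerate — paths can cheapen transport by
shrinking the surface mid-path, and the infimum may not be attained — so
`a0`-only settings are used in this code base only for closed-form test
fixtures, never as a recommended analysis configuration.

The a2 term is weighted by `vol_v` by default, consistent with the
zeroth-order term; `a2_weighting="none"` exposes the raw integrated sum.
Under simultaneous scaling `V→sV, h→sh` the terms scale as `s⁴` (a0), `s²`
(first-order), and `s⁴`/`s²` (a2 with/without vertex-area weighting).

## Varifold fidelity

A mesh maps to one weighted Dirac atom per face at the barycenter, with the
unit normal as orientation, the face area as mass, and an optional weight
`ρ_f ∈ [0,1]`. Two such measures are compared through the squared RKHS
distance of the separable kernel

    k((x,n),(x',n')) = exp(−|x−x'|²/σ²) · (n·n')²,

the Gaussian × Cauchy–Binet default (orientation-blind; a `linear` zonal
kernel that sees orientation is also available). Evaluation is exact
double-precision summation over all face pairs — quadratic in the face
count, which is the dominant cost of relaxed matching; pairwise distances
are formed through Gram matrices so memory stays O(m_a·m_b).

`σ` has length units and must suit the data scale: too small and the
kernel sees nothing (the documented cause of non-finite objectives, which
the solvers abort on with that diagnostic); too large and it blurs shape
differences. The shipped heuristic is `σ = 0.2 ×` the target's bounding-box
diagonal; every experiment here states its σ.

## Geodesic solvers

The energy of a PL path uses the left-endpoint rule; it is therefore exact
for metric-constant deformations (e.g. pure translations under `a0`) at
every N, first-order in 1/N otherwise, and time-reversal symmetric only up
to O(1/N).

* **Fixed-correspondence BVP** — minimize E over interior breakpoints with
  L-BFGS from linear interpolation, with a doubling-in-time
  multiresolution schedule (2 → 4 → … → N).
* **Relaxed BVP** — add `λ1 ×` the varifold discrepancy at the free
  endpoint (asymmetric form, start clamped to the source) and optionally
  `λ0 ×` a discrepancy at a free start (symmetric form, whose path
  combinatorics is a user template, defaulting to the source). Defaults:
  `λ0 = λ1 = 1/⟨μ_src, μ_src⟩`, which makes the fidelity O(1) relative to
  the varifold mass at the start of optimization; serious matching runs
  should raise λ to push the residual down. Initialization is the
  constant-at-source path. The multiresolution schedule may also refine
  the mesh (1→4 midpoint subdivision applied to every breakpoint).
* **IVP** — discrete geodesic shooting: `V_0 = q`, `V_1 = q + h/N`, then
  each `V_{i+1}` solves the three-term stationarity system `F = 0` stating
  that `V_i` is the geodesic midpoint of its neighbours. `F` is itself the
  gradient of a two-segment energy, so minimizing `‖F‖²` needs second
  derivatives; the autodiff engine supplies them exactly. Steps start from
  the linear extrapolation `2V_i − V_{i−1}` and are declared converged at
  `‖F‖² ≤ 1e−8 × ‖F_drive‖²`, where `F_drive` is the constant first term
  (the metric applied to the incoming velocity); unconverged steps are
  flagged but the path is still returned.

Because the IVP solves exactly the stationarity system a BVP minimizer
satisfies, BVP→IVP round trips reproduce the BVP endpoint to optimizer
precision (~1e−7 of the shape diameter on the test fixtures) at every N —
there is no discretization gap between the two discrete problems, only
solver tolerance.

All optimizations use scipy's L-BFGS-B (history 10, gradient tolerance
1e−7, up to 500 iterations per stage by default) with exact gradients from
the in-package reverse-mode autodiff engine; the solvers are deterministic
given their inputs.

## Statistics

* **Karcher mean** — the stochastic iterative geodesic centroid: at
  iteration i, move the estimate to the point at time `1/(i+1)` of the
  geodesic toward a uniformly drawn datum (with replacement, seeded);
  `N_iter = 3K` by default. With the step sequence `1/(i+1)` the final
  estimate is algebraically the average of the initialization and the
  `N_iter` draws, so for K=2 translated copies its deviation from the
  midpoint is bounded by `0.43|τ|` for any draw sequence — the test fixture
  uses `|τ| = 0.1 ×` diameter so the 5 %-of-diameter check holds
  deterministically. Parametrized data default to the Euclidean vertex
  mean as initialization; inconsistently meshed data require an init mesh,
  which fixes the mean's combinatorics, and use the relaxed solver.
* **Tangent PCA** — solve one BVP per datum from the reference, take
  finite-difference initial velocities, eigendecompose the centered K×K
  Gram matrix under `G_ref`. Components `w_ℓ = Σ_k v_{ℓ,k}(h_k − h̄)` are
  G-orthogonal with squared norms λ_ℓ; principal geodesics are shot along
  `±λ_ℓ w_ℓ` (the `sqrt_lambda` scaling — the conventional standard
  deviation — is exposed as an option). The rank-1 validation cohort uses
  N=1 geodesics, for which the discrete log map is exactly the vertex
  chord and pure translations give an exactly rank-1 Gram matrix.
* **MDS** — stress is the root-sum-of-squares mismatch between the input
  geodesic distances and the embedding's Euclidean distances. Classical
  scaling provides the start (exact on Euclidean-realizable matrices);
  SMACOF majorization iterations (scikit-learn's implementation) refine
  it. The embedding is reported up to rigid motion only. Distance matrices
  come from the symmetric relaxed solver, solved once per pair and
  mirrored (exact up to the O(1/N) time-rule asymmetry).
* **Schild's ladder** — the base geodesic is split into `n_rungs` uniform
  segments; each rung builds one geodesic parallelogram (midpoint by BVP,
  diagonal doubled by IVP) and the transported vector is the final log
  map. One parallelogram per segment is this package's reading of the
  ladder; it is first-order, and the tests assert only that the metric
  norm drift shrinks as rungs are refined.

## Partial matching

Weighted matching minimizes path energy plus two fidelity terms: the start
of the path, carrying the *fixed* source weights ρ0, against the source;
and the end, carrying the *estimated* weights ρ, against the target. Only
the transformed source's weights are estimated (target-side or dual-weight
estimation invites the trivial all-zero solution and is deliberately not
offered). ρ is a direct box-constrained variable of L-BFGS-B, initialized
at ρ0; at ρ ≡ 1 the objective degenerates exactly to the unweighted
symmetric relaxed objective. Optional penalties — a double-well term
`Σ (ρ(ρ−1))² vol_f` and total variation of ρ − ρ0 over interior edges —
are off by default and their balancing weights are user inputs. Weights
model erasure only: the mesh topology of the evolving path never changes.

## Synthetic data

All test inputs are generated: planes, icospheres and UV spheres (the same
geometry under two combinatorics — the remeshing test bed), tori, open
tubes, ellipsoids, plus seeded jitter, rigid motions, smooth bends and
component deletion (two spheres vs one — the partial-observation test
bed). These fixtures reproduce the *regimes* that matter for the method —
inconsistent meshing, boundaries, genus, missing parts, noise — but not the
scale (10²–10³ vertices here vs 10⁴–10⁵ for real scans), the scanner noise
statistics, or the anatomical shape variability of real cohorts; passing
tests validate the machinery and its invariances, not cohort-level
scientific claims. Problem sizes in the shipped suite and acceptance
script (icospheres at subdivision ≤ 2, N ≤ 8, K ≤ 4) were chosen so each
pipeline runs in seconds to a couple of minutes on one CPU.

## Open choices

Decisions the underlying theory leaves open, fixed here as follows:

* boundary edges contribute their single opposite cotangent;
* the a2 term is vertex-area-weighted by default (flag to disable);
* the relaxed solver's λ defaults normalize by the source's varifold mass;
* the IVP stopping rule is relative (`1e−8` of the driving term's norm²);
* Schild's ladder uses one parallelogram per uniform segment;
* σ defaults to 0.2 × target bbox diagonal when unset.

## Known limitations

Quadratic varifold cost makes >10⁴-face matching slow on one CPU (a GPU
kernel engine would drop in naturally behind `varifold`). The relaxed
solver's constant-at-source initialization can stall on large deformations
— a coarser template plus the spatial multires schedule is the remedy. The
L² (`a0`-only) limit of the metric family is degenerate by construction.
Rotational/translational pre-alignment is the user's responsibility (the
metric and fidelity are equivariant, not alignment-seeking). Weighted
matching compares across topologies by erasure; it does not produce meshes
of a different topology.
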