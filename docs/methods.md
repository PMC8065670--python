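# Methods

## Problem and model

Given `m` views `X^v ∈ R^{d_v×n}` of the same `n` samples, the method learns,
jointly: a `k`-sparse column-stochastic affinity graph `S^v` per view, a
spectral embedding `F^v ∈ R^{n×c}` per view, positive view weights `w_v`, a
consensus graph `Z`, and its embedding `U ∈ R^{n×c}`. The joint objective is

    min  Σ_v [ 2 Tr(F^vᵀ L^v F^v) + α‖S^v‖_F² + w_v‖Z − S^v‖_F² ] + 2β Tr(Uᵀ L_Z U)

subject to orthonormal embeddings and columnwise simplex constraints with
zero diagonals on `S^v` and `Z`. `L` is always the unnormalized Laplacian of
the *symmetrized* matrix `(A + Aᵀ)/2`; the stored graphs keep their
(possibly asymmetric) column-stochastic form because the constraints are
columnwise.

Two standard facts drive the construction. The multiplicity of the zero
eigenvalue of a graph Laplacian equals the number of connected components of
the graph; and by the Ky Fan theorem, `min_{FᵀF=I} Tr(FᵀLF)` equals the sum
of the `c` smallest eigenvalues of `L`. Minimizing the trace term therefore
pushes those eigenvalues toward zero, i.e. toward `rank(L_Z) = n − c`,
making the clusters readable directly as the components of `Z`.

## The five block updates

Each update is an exact minimizer of the objective in one block:

1. **Affinity `S^v`** (per column `j`): with embedding distances
   `p_ij = ‖f_i − f_j‖²` and candidate cost `g_i = p_ij/2 − w_v z_ij`, rank
   candidates `i ≠ j` by `g` ascending (ties broken by sample index), keep
   the best `k`, set `δ_j = k g_(k+1) − Σ_{l≤k} g_(l)` and project
   `(w_v z_j − p_j/2)/δ_j` onto the simplex restricted to that support. The
   choice of `δ_j` places the `(k+1)`-th candidate exactly at the zero
   threshold, so the column has exactly `k` nonzeros and the implicit ridge
   strength is `α_j = δ_j − w_v`. If consensus mass concentrates outside
   the top-`k` set, `δ_j` can go non-positive; it is clamped to `1e−12`
   with a warning. The projection argument is centered (projection is
   invariant to adding a constant) so the clamped branch stays numerically
   exact.
2. **Embedding `F^v`**: the `c` eigenvectors of `L^v` with smallest
   eigenvalues (dense symmetric solver, ascending order, sign fixed so each
   eigenvector's largest-magnitude entry is positive — reproducible across
   runs; behavior under a degenerate eigenvalue at position `c` is
   solver-dependent by nature).
3. **Weights**: `w_v = 1/(2‖Z − S^v‖_F)`, the self-weighting fixed point of
   the implicit sum-of-distances objective. Distances are floored at
   `1e−12`, so a view identical to the consensus gets the largest finite
   weight. The squared variant `1/(2‖Z − S^v‖_F²)` is available as
   `weight_exponent=2`.
4. **Consensus `Z`** (per column): projection of
   `(Σ_v w_v s_j^v − (β/2) q_j)/Σ_v w_v` onto the zero-diagonal simplex,
   where `q_ij = ‖u_i − u_j‖²`. `Z` is *not* re-sparsified to `k` entries;
   sparsity emerges from the projection.
5. **Fused embedding `U`**: as step 2 on `L_Z`.

All columnwise closed forms are verified in the test suite against a
generic SLSQP quadratic-program solver and a brute-force active-set
enumeration of the simplex projection.

## β adaptation and convergence

`β` starts at `beta0` (default 1) and is adapted after every iteration:
halved when `Z` has more than `c` components, doubled when fewer, untouched
on target, clamped to `[2⁻²⁰, 2²⁰]`. The wide range gives the
doubling/halving rule head-room; the dynamic rule, not the initial value,
does the tuning. Convergence requires exactly `c` components on **two
consecutive** iterations, which guards against β flip-flop oscillation.
Component decisions use combinatorial connected components on the support
`(Z + Zᵀ)/2 > 1e−8` rather than eigenvalue counting, which is numerically
fragile near convergence; the two agree at the reported solutions and that
agreement is itself tested.

If `max_iter` (default 100) is reached off target, the run is flagged
`converged=False` and labels are still forced to `c` clusters: components
are merged pairwise by strongest cross-component similarity when there are
too many, or the largest component is split by spectral bisection of its
consensus submatrix when there are too few. This is a flagged fallback,
never silent. An optional `min_cluster_size` check (default off) flags —
but does not alter — solutions with clusters smaller than the threshold.

## Objective trace

`SolverState.objective_trace` records, per iteration,
`Σ_v [2 Tr(F^vᵀL^vF^v) + w_v‖Z − S^v‖_F²] + 2β Tr(UᵀL_ZU)`. The ridge
terms `Σ_j α_j‖s_j‖²` are omitted from the trace because the implicit
`α_j` are re-calibrated every iteration by the exact-`k` rule (and can go
negative once view weights grow near convergence), which would make values
incomparable across iterations; `objective(state, include_ridge=True)`
returns the full value at the current strengths. On seeded runs the trace
is non-increasing (tolerance `1e−8` per step) once β has stabilized, and
this is asserted in the tests.

## Synthetic data

`make_multiview_blobs` generates `c` balanced clusters observed in `m`
views: per view, cluster centers sit on a random orthogonal frame scaled by
`separation` (pairwise center distance `separation·√2`; views with fewer
dimensions than clusters fall back to random directions rescaled to the
same minimum separation) plus isotropic Gaussian noise. Defaults —
30 samples per cluster, `c = 3`, `m = 3`, 10 dimensions per view,
`separation = 10`, `noise_sd = 1` — give the well-separated regime
(separation/noise = 10) in which exact recovery is the expected outcome and
is asserted over 20 seeds. A *corrupted* view has its cluster assignment
shuffled before generation: it retains internal cluster geometry but is
independent of the true labels, which is the failure mode the
inverse-distance weighting is designed to absorb.

The generator emulates only the geometry the model assumes — separated
point clouds with independent per-view noise. It does not simulate omics
marginal distributions (counts, methylation betas), batch effects, or
missing data, so passing tests demonstrate correctness of the optimization
and its claimed properties, not performance on real multi-omics cohorts.
The frozen 12-sample fixture in `datasets.make_worked_fixture` hard-codes
one tiny instance (rounded to 4 decimals) for bit-exact regression tests.

Problem sizes throughout the test and acceptance runs (n = 90–300,
20 replicates) were chosen as the smallest sizes at which the asserted
properties are sharp; all runs complete in seconds.

## Numerical choices and limitations

- Distances are squared Euclidean; no kernel option.
- Ties anywhere (neighbor ranking, eigenvector signs, component
  numbering) break by first index, making runs bit-identical.
- Duplicated points beyond the neighbor budget get uniform weights over the
  zero-distance set; an all-equidistant column falls back to uniform `1/k`
  with a warning.
- Metrics: ACC via Hungarian assignment on the contingency table (handles
  unequal cluster counts by rectangular assignment); NMI with natural logs
  and geometric-mean normalization by default (`max` and `arithmetic`
  available); both-trivial partitions score NMI 1, exactly one trivial
  scores 0.
- The method expects continuous features; binary or categorical layers
  (mutation calls, copy-number states) are not meaningfully served by
  Euclidean adaptive neighbors. Dense eigendecompositions make the cost
  `O(n³)` per iteration, fine for cohort-scale `n` (hundreds), not for
  `n ≫ 10⁴`. The number of clusters `c` must be supplied.
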