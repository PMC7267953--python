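# Methods

## The navigation game and the optimal connectome

Nodes are brain regions with fixed spatial positions; the only geometric
input anywhere in the package is a symmetric inter-node distance matrix
`D` with zero diagonal and strictly positive off-diagonal entries
(Euclidean distances between region centroids by default, but any
user-supplied matrix — e.g. surface geodesics computed elsewhere — is
accepted unchanged).

Communication is modelled as *greedy routing*: a message at node `x`
bound for target `t` hops to the neighbour of `x` closest to `t`, and is
lost if no neighbour is strictly closer.  Each node `u` plays a
wiring-cost game: it must choose a connection set such that greedy
routing from `u` reaches every other node, using as few connections as
possible.  The set of targets reachable from `u` through first hop `v`
is

    S_v^u = { w ≠ u : D(v, w) < D(u, w) },

and the optimal strategy of `u` is a *minimum set cover* of `V \ {u}` by
the sets `S_v^u`.  Since every target `w` lies in its own set `S_w^u`,
the cover always exists.  Pooling every node's optimal strategy and
symmetrizing gives the Nash-equilibrium network (NNG): no node can
unilaterally drop a connection without losing navigability.  By
construction the equilibrium network has greedy-routing success for all
ordered pairs; the test suite checks this exhaustively on every built
instance.

The cover is solved **exactly** — not greedily — as a 0/1 integer
program (HiGHS via `scipy.optimize.milp`, `mip_rel_gap = 0`), with an
exhaustive-enumeration solver for small instances that doubles as the
test oracle.  Minimum covers need not be unique; for reproducibility the
solver prefers the lexicographically smallest chosen-neighbour index
set, encoded as a cost perturbation `1 − 2^−(v+2)` per candidate `v`
(total perturbation < ½, so cardinality optimality is untouched).  The
perturbation is numerically meaningful up to index ≈ 45; beyond that,
determinism rests on the deterministic solver.  `|M|` counts
*undirected* edges of the symmetrized union, matching how structural
matrices are compared.

Overlaying a measured structural network (edge = strictly nonzero
weight; GFA-like values in (0, 1] or streamline counts) on the NNG
partitions the edge universe: **optimal** edges (T) exist in both,
**nonoptimal** edges exist only in the structural network, **false
positives** (F) only in the NNG.  Optimality = |T|/|M|, with
|T| + |F| = |M| by construction.  A per-block mode plays the game
separately inside node blocks (e.g. hemispheres, where geodesic
distances are only defined within a surface) and equals the
block-diagonal composition exactly.

Regional optimality (RO) is the per-node optimal minus nonoptimal
degree; normalized RO divides by the node's total structural degree and
lies in [−1, 1].  False-positive edges never enter degrees or ratio
denominators (they do not exist in the real network), and zero
denominators are reported as NaN rather than 0 — "no edges" is not "no
optimal edges".

## Spectral structure→function map

Functional connectivity is modelled as a rotated matrix polynomial of
the structural matrix:

    F̂ = R (Σ_{r=0}^{k} a_r S^r) Rᵀ,   RᵀR = I, det R = +1.

Powers of `S` count walks, so order `k` controls the path lengths that
contribute; the default `k = 5` is where prediction accuracy plateaus in
this model family.  For symmetric `S` and `F` the Frobenius objective
has a closed-form minimizer within this class: sort both
eigendecompositions descending, set `R = U_F U_Sᵀ`, and regress F's
sorted eigenvalues on the Vandermonde matrix of S's sorted eigenvalues
(OLS, powers 0..k).  Determinant correction flips the sign of the
eigenvector attached to F's smallest-magnitude eigenvalue, which leaves
every prediction invariant.  Nested Vandermonde designs make the
residual monotone non-increasing in `k`.

Numerical notes.  Descending-*value* eigenvalue pairing (not magnitude)
preserves the order statistics of correlation matrices.  This pairing
identifies the planted forward model only when the generating polynomial
is monotone increasing on S's spectrum — otherwise sorted F-eigenvalues
pair with the wrong S-eigenvalues; the synthetic generator's default
coefficients are chosen globally monotone for exactly this reason (see
below).  Repeated eigenvalues make `R` non-unique, but `F̂` depends only
on the eigenspaces and is unchanged.  `k ≥ n` produces a rank-deficient
design; the fit warns and falls back to minimum-norm least squares.
Predictions are scored by Pearson correlation over the strictly upper
triangle (diagonal excluded); a constant triangle yields NaN, never a
crash.

## Betti-0 persistence score

Both matrices are thresholded at every edge density λ ∈ [0, 1]: keep the
⌊λE⌋ largest off-diagonal entries (E = n(n−1)/2) and count connected
components β0(λ) by incremental union-find.  The score is

    SSE_β = (1/n²) ∫₀¹ (β0(λ) − β̂0(λ))² dλ,

integrated by the trapezoidal rule on the density grid.  The default
grid has one step per edge rank, representing the piecewise-constant
curves exactly; coarser grids subsample the same exact curve.  Edges are
ranked by signed weight descending (strongest positive correlations
first), ties broken by (i, j) index; an `absolute` flag ranks by
magnitude instead.  Because the construction is rank-based, the score is
invariant under common strictly increasing transforms of both inputs.

## Distance controls

Two controls separate "optimal wiring" from "merely short wiring":

1. **Generative null.**  Networks grown edge-by-edge with probability
   ∝ `dist^−η` (probabilities renormalized over the remaining non-edges
   after each addition), matched to the real network's edge count.  The
   exponent is fitted by stochastic search: uniform η samples over
   [−1, 10] (64 by default; the searches in the shipped experiments use
   20, which recovers a planted η* = 3 to within ±1), each scored by an
   energy = max Kolmogorov–Smirnov distance between real and synthetic
   distributions of degree, clustering coefficient, betweenness and edge
   length; then two refinement rounds resample η from one-dimensional
   Voronoi cells (nearest-neighbour intervals of the sampled η's) chosen
   with probability ∝ 1/energy.  The returned fit is the argmin over all
   evaluated networks.  The four-statistic energy follows the generative
   connectome-modelling literature; the subset is configurable.

2. **Distance regression.**  `F_new = F − D·(D⁺·F)` with `D⁺` the
   Moore–Penrose pseudoinverse: each column of a predicted matrix is
   projected onto the orthogonal complement of the distance matrix's
   column space.  The projector is idempotent and its residuals are
   orthogonal to D's columns to machine precision.  The residual is not
   re-symmetrized by default (the formula is columnwise); a flag
   averages with the transpose.

## Expression PLS

Normalized RO per region (response) is regressed on a region×gene
expression matrix (predictors) by PLS1 (NIPALS, via scikit-learn behind
the module surface).  Gene columns are z-scored by default because
microarray scales are heterogeneous; this can be disabled.  Reported per
component: variance explained in the response (nested OLS on the score
columns) and in the predictor block, plus the Spearman correlation of
component-1 scores with the response.  Significance uses permutation of
the response's region labels: the null statistic is the component-1
variance explained, and p = (1 + #{null ≥ observed})/(1 + n_perm) — the
add-one estimator, never exactly zero.  The permutation path exploits
the closed form of the first PLS1 component (w ∝ Xᵀy), vectorized over
permutations and verified against the iterative fit in a unit test.
Ten-fold cross-validated predictive R² per component count is reported
as a diagnostic only; component 1 is always the reported component.
Plain label permutation does not preserve spatial autocorrelation;
spatially constrained nulls are out of scope.

## Synthetic data: what it emulates and what it does not

The generators plant ground truth for every downstream stage:

* **Layouts** — uniform points in a 100-unit cube, or two Gaussian
  blobs; coincident points are resampled.
* **Structural networks** — the NNG over the layout seeds the edge set;
  each core edge is dropped with probability `p_drop` (these are exactly
  the false positives a later classification must find) and
  ⌈`p_extra`·m⌉ extra edges are planted with probability ∝ distance
  (long-range bias), becoming the nonoptimal class.  Weights are
  `clip(exp(−d/d₀) + ε, 10⁻³, 1]` with `d₀` the median pairwise distance
  and ε ~ U(0, 0.05): bounded, GFA-like, decreasing with distance; the
  precise shape is irrelevant to the downstream math.  Defaults
  `p_extra = 0.3`, `p_drop = 0.1` give cohorts whose optimality is high
  but strictly below 1, qualitatively matching measured connectomes.
* **Functional matrices** — the forward model itself, with an identity
  or Haar-random special-orthogonal rotation and independent symmetric
  Gaussian noise (default sd 0.05, small relative to unit-scale
  structural weights).  Default coefficients
  a = (0, 1, 0.05, 0.3, 0, 0.1): degree 5, and
  p′(x) = 1 + 0.1x + 0.9x² + 0.5x⁴ > 0 everywhere, so the planted map is
  identifiable under sorted-eigenvalue pairing (see above).
* **Rest/task pairs** — rest is the forward model of the optimal-core
  submatrix alone; task is the forward model of a mixture that shifts
  communication energy onto the long-range class.  Because weights decay
  with distance, the nonoptimal submatrix carries little spectral energy
  on its own; it is rescaled to the core's Frobenius norm before the
  gains (×2 nonoptimal, ×0.25 optimal) apply, so the planted task state
  is genuinely nonoptimal-dominated regardless of how many extra edges
  exist.  This construct is qualitative plumbing: it guarantees the
  *orderings* (optimal-masked beats nonoptimal-masked at rest;
  nonoptimal-masked improves from rest to task) and nothing more.
* **Expression** — `n_signal` gene columns equal RO plus noise
  (default sd 0.5, a moderate signal-to-noise regime), the rest are
  standard-normal noise; names (`gene_s…`/`gene_n…`) carry the ground
  truth, column order is shuffled.
* **Partitions** — random labels with every network used at least once.

All generators are deterministic under a fixed seed; cohorts derive
per-subject seeds from one master seed via `SeedSequence` spawning.

None of this mimics MRI physics, tractography bias, head motion, or
real gene co-expression covariance.  Passing tests demonstrate that the
*methods* are implemented correctly and identify planted structure under
their own assumptions — not that those assumptions hold in measured
connectomes, where the published optimality (~0.79) and prediction
correlations (~0.84–0.97) sit well below the near-perfect recovery seen
on noiseless synthetic data.

## Group statistics

Masked prediction scores are compared by one-way repeated-measures ANOVA
with Greenhouse–Geisser correction and Bonferroni-adjusted pairwise post
hocs (pingouin), or by paired / two-sample t-tests (scipy).  Degenerate
inputs are handled explicitly: identical scores everywhere report F = 0
with all post hoc p = 1, and a constant nonzero paired difference is
flagged as zero-within-pair-variance with t = ±∞, p = 0.

## Problem sizes and design choices

The shipped experiments use cohorts of 10 subjects × 40 nodes,
generative-model recovery at 100 nodes / 300 edges, and PLS at 60
regions × 100 genes with 199–999 permutations — sizes at which every
planted property is comfortably detectable and a full run completes in
well under a minute on one core.  The package deliberately exposes the
fitted components as model/results pairs (`SpectralMap`,
`DistanceGenerativeModel`, `ExpressionPLS` → results objects with
`summary()`), while the game construction, classification, partition
metrics and homology scoring — deterministic constructions, not fits —
remain plain functions and dataclasses.

Known limitations: the set-cover ILP is exact but its tie-break is only
numerically lexicographic up to index ≈ 45; the energy landscape of the
generative fit is stochastic, so the recovered η is reproducible only
under a fixed seed; PLS label permutation ignores spatial
autocorrelation; and the homology score is limited to β0 (no higher
Betti numbers or persistence diagrams).
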