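# Methods

## Pre-processing (View 1)

Four steps, in order, on a genes × cells matrix:

1. **Conditional log transform.** If the value range (max − min) exceeds
   100 the matrix is replaced by log2(x + 1); otherwise it is left
   untouched. The pseudocount is +1. The rule is idempotent: once the
   range collapses below the threshold a second application is a no-op.
2. **Sparse-gene filter.** A gene is removed when its fraction of zero
   cells is *strictly greater* than 0.95 (a gene zero in exactly 95 of 100
   cells is kept). Removing every gene is an error, not a silent empty
   matrix.
3. **Size-factor normalization.** Library size s_i is the column sum of
   the (possibly log-transformed) matrix; each cell is divided by
   s_i / s_m with s_m the median library size, so afterwards every cell's
   library size equals s_m exactly. A zero library size aborts with the
   offending cell named.
4. **Highly-variable genes.** The top 2000 genes by variance of the
   normalized values (a variance/mean dispersion score is available via
   `hvg_method="dispersion"`), ties broken by ascending gene index,
   retained in original gene order. The variability metric is a design
   choice of this package; variance of the normalized values is the
   simplest fully reproducible option.

## View construction

- **Pathway view.** For each cell, genes are ranked by expression
  descending with ties kept in original gene order (deterministic, unlike
  tools that randomize ties). A gene set's score is the area under its
  recovery curve over the top ⌈0.05·G⌉ ranks, normalized by the maximum
  achievable area, hence in [0, 1]. Scoring uses the normalized pre-HVG
  matrix by default: the HVG step keeps 2000 genes and would empty most
  gene sets; `pathway_on_raw=True` scores the raw input instead. Set
  members absent from the matrix are dropped; a set with no overlap scores
  zero with a warning.
- **PCA view.** Gene means subtracted, cells projected onto the top-d
  principal axes via SVD. Deterministic sign convention: each axis's
  largest-magnitude loading is made positive. Requests beyond the rank are
  truncated with a warning.
- **Diffusion-map view.** Gaussian kernel K_ij = exp(−‖x_i−x_j‖²/2σ²),
  Markov normalization P = D⁻¹K, coordinates λ_l^t ψ_l for the top-d
  non-trivial right eigenvectors (computed through the symmetric conjugate
  D^{-1/2}KD^{-1/2}; the constant eigenvector at λ = 1 is skipped). The
  bandwidth default is the **median pairwise distance** rather than a fixed
  σ = 1: on ~2000-dimensional log-expression data squared distances are in
  the hundreds, exp(−d²/2) underflows, and a unit bandwidth degenerates the
  kernel to the identity. σ and t remain configurable (`dm_sigma`,
  `dm_t`); t defaults to 1.
- **Dimensionality.** When not overridden, the PCA/DM dimension is the
  Levina–Bickel maximum-likelihood intrinsic dimension of the pre-processed
  matrix, averaged over neighbor counts k = 6..12 and over cells, rounded
  and clipped to [1, min(d, n−1)]. Duplicate points are handled by
  flooring neighbor distances at machine-epsilon scale with a warning.
- Views are assembled in the fixed order expression → pathway → pca → dm;
  any subset reproduces the ablation variants (e.g. all but `pathway`).
  A cell-order mismatch between views is a hard failure.

## Graph learning

Row i of view v's similarity graph solves

    min_{s on simplex, s_ii=0}  Σ_j cost_ij s_ij + (γ_i + w_v) ‖s_i‖²

with cost = squared distance b_ij at initialization (w_v = 0) and the
combined cost e_ij − 2 w_v u_ij thereafter. γ_i is set per row to
(k·c_(k+1) − Σ_{h≤k} c_ih)/2 minus w_v, the critical value at which the
solution has exactly k nonzeros, giving the closed form
s_ij = (c_(k+1) − c_ij)/(k·c_(k+1) − Σ_{h≤k} c_ih) over the k
smallest-cost neighbors. Design choices:

- **Neighbor ordering** uses the combined cost (the quantity the row
  subproblem penalizes), under which the closed form is provably the exact
  simplex-QP minimizer and never negative. Ordering by plain distance is
  available (`order_by="expression"`) and clamps/renormalizes when the
  printed formula goes negative.
- **Ties** at the k/(k+1) boundary break by ascending column index
  (stable sort). A degenerate denominator (k nearest all equidistant with
  the (k+1)-th) falls back to a uniform 1/k row with a warning.
- **Neighbor count** k defaults to 5 below 3000 cells and 15 at or above,
  mirroring the observed stability of the method across dataset sizes.
- **View weights**: w_v = 1/(2‖U−S^v‖_F), residual floored at 1e−10 so an
  exactly matching view gets a large finite weight; initialized at 1/m.

## Unified graph and rank constraint

- **U-update.** With d_ij = ‖f_i − f_j‖² and q^v = s_i^v − λ/(2 m w_v) d_i,
  each row of U is the Euclidean projection of mean_v(q^v) onto the
  probability simplex. The projection shifts the input along the all-ones
  direction to sum 1 (the projection is invariant to such shifts) and then
  finds the threshold by safeguarded Newton iteration on the piecewise
  linear root function, to |f| < 1e−12 or 100 iterations.
- **F-update.** Eigenvectors of the c smallest eigenvalues of L_U, column
  signs fixed by the largest-magnitude entry; eigenvalue ties resolve by
  solver order and are then sign-fixed, so runs are reproducible.
- **λ adaptation.** λ starts at the mean of the initial per-row γ_i (a
  scale-matched default) and is steered by the zero-eigenvalue count z of
  L_U: doubled while z < c, halved (with the U- and F-updates redone at
  the smaller value) when z > c, converged at z = c. Zero eigenvalues are
  counted below 1e−10·n; graph edges below 1e−8 are treated as absent when
  components are extracted. Both tolerances are configurable.
- **Initialization.** U is the simplex-projected weighted mean of the
  initial S^v — the λ→0 fixed point of the U-update, feasible by
  construction.
- **Update order** per iteration: {S^v} → w → U → F → λ.
- **Non-convergence.** If after `max_iter` (default 50) sweeps the graph
  does not have exactly c components, labels fall back to seeded k-means
  on the rows of F and the result is flagged (`fallback_used`);
  `fallback="error"` raises instead.

### Descent property

The printed objective treats w_v, γ and λ as model-computed parameters,
not free variables: refreshing w mid-sweep can raise the weighted
Frobenius term when residuals shrink (that refresh descends a
sum-of-norms surrogate instead). The descent guarantee that is actually
testable is therefore stated for the exact block-coordinate sweep
S → U → F at frozen γ, w, λ (`fusion.coordinate_sweep`, with
`update_similarity_graph(..., gamma_rows=...)` as the exact fixed-γ row
minimizer); the test suite verifies it on 20 random states.

## Metrics

CA is the best one-to-one cluster matching (Hungarian algorithm on the
contingency table, padded when cluster counts differ). NMI normalizes
mutual information by the arithmetic mean of the partition entropies
(sqrt/max selectable); degenerate single-cluster cases return 0 by
convention. ARI is the pair-counting adjusted Rand index (scikit-learn),
cross-checked in the tests against an O(n²) brute-force pair counter.

## Synthetic data: what it emulates and what it does not

The generator produces c clusters of cells (equal sizes by default, exact
to rounding; Dirichlet imbalance optional). Gene baselines are log-normal
(median ≈ 1.5 counts, floored at 0.2 so essentially no gene fails the 95%
zero filter at moderate dropout); each cluster owns a disjoint marker
panel (default n_genes/20 genes) whose means are multiplied by the effect
size. Counts are Poisson by default (negative binomial with dispersion
parameter selectable), then thinned by independent per-entry dropout.
Pathways sample 30 genes each; 40% of them draw 70% of their genes from
one cluster's markers, so pathway scores carry cluster signal the way
curated databases do for real cell types.

The reference study conditions used across the tests and the acceptance
script are 300 cells (200 for the graph-initialization measurement),
1000 genes, 3 clusters, effect 8, dropout 0.3 — sizes at which the full
pipeline runs in seconds on one core. What passing on this generator does
*not* show: robustness to batch effects, library-size gradients
confounded with type, overlapping marker programs, rare populations, or
mis-specified cluster number c — none of which the generator produces.
Effect 8 is an easy, well-separated regime (k-means on log counts already
recovers it); the interesting checks are the structural ones (exact
k-sparsity, simplex feasibility, rank-constraint convergence) and the
graceful degradation at effect 2.

## Known limitations

- All-pairs distances and dense eigendecompositions are O(n²)–O(n³);
  intended for desk-scale n (thousands), not atlas scale.
- c is taken as given; the method does not select the number of clusters.
- S^v matrices are not symmetrized (only L_U symmetrizes U); the learned
  graphs are directed row-stochastic objects.
- The λ doubling/halving rule usually terminates quickly but is not
  guaranteed to; the k-means fallback is flagged explicitly when it fires.
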