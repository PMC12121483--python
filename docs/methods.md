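# Methods

## Model and procedure

`appcluster` performs recursive divisive clustering of an n × d numeric
event matrix.  Each recursion step examines all C(d, 2) orthogonal 2D
projections of the current subset, searches each projection for the
decision boundary with the smallest integrated density, ranks the
candidate boundaries by the Calinski–Harabasz (CH) index of the 2-way
split they induce, splits on the global best, and recurses on both sides.
The method assumes that cluster structure is visible in at least one
axis-aligned 2D projection: populations separated only by oblique
combinations of many features (no rotation search is performed) or by
higher-order interactions will not be split.

The boundary search is a discrete analogue of a variational problem.  The
subset is mapped onto the unit square (per-axis affine rescaling by the
subset-local min/max, recomputed at every step, which makes the whole
pipeline invariant to positive per-axis affine transforms of the input).
A parabolic gravity potential H_g(y, q) = (y − y₀)² anchored at
y₀ = q (unit coordinates) is added to the smoothed density H with coupling
k = β·(max H − min H)/max H_g, and for each q on a lattice the path
minimising the column sum of H₁ = H + k·H_g is found.  The path's action
S(q) sums the *raw* H along the path — the gravity term steers the search
but must not contaminate the valley score.  Strict interior local minima
of S over the q lattice are the boundary candidates.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_cluster_size` | required | events | smallest population expected; branches under twice this size are never split, and no candidate may leave either side below it |
| `sigma` | 1.0 | bins | Gaussian smoothing width of the 2D histogram; also scales the Mann bin count |
| `beta` | 0.1 | — | gravity strength (10% of the density's dynamic range at the potential's maximum) |
| `dq` | 0.1 | — | gravity-level lattice step; q ∈ {0, 0.1, …, 1} |
| `bins_override` | none | bins | fixed per-axis bin count replacing Mann's rule (useful to mirror a fixed "bin size" workflow on cytometry data) |
| `step_limit` | 1 | bins | maximum per-column row move of the boundary path |
| `max_depth` | off | — | safety cap only; the size rule already guarantees termination |

The smoothing width default of 1 bin is the smallest width that still
regularises Poisson bin noise without flattening genuine valleys; the
relationship between the bin count produced by Mann's rule and any fixed
externally chosen bin size is left to `bins_override`.

## Numerical choices

- **Mann bin count** N = 4σ[3(n−1)²/4]^0.1 is rounded half away from zero
  and clamped to ≥ 4 (a 2×2 grid cannot host a path).
- **Binning** uses half-open bins [e_i, e_{i+1}) with the final bin
  closed, 0-based indices.
- **Smoothing boundary rule**: each source bin's truncated Gaussian
  kernel is renormalised to unit mass inside the grid, so the histogram
  total always equals the event count exactly.  Near edges this slightly
  re-weights bins (a constant field is not exactly preserved there); mass
  conservation was preferred because the action compares absolute density
  levels across q.
- **Dynamic programming**: the continuous extremal is discretised as a
  minimum-cost path over grid columns with per-column row moves in
  {−step_limit, …, +step_limit}; only the start row (the bin containing
  y₀) is anchored, the end row is free.  Cost ties are broken toward the
  row nearest y₀, then toward the lower row index — consistent with the
  gravity prior and fully deterministic.
- **Action quadrature** is bin-center sampling with Δx = 1/N.
- **q lattice endpoints** (0 and 1) can never satisfy the strict
  two-sided local-minimum condition and are never candidates.
- **CH index** is computed in the 2D unit-square projection where the
  boundary lives (not the full feature space); a split with zero
  within-group dispersion scores +inf and outranks all finite scores.
- **Point assignment**: an event goes below the boundary iff its
  unit-square y does not exceed the path's bin-center ordinate in its
  x-column; on-boundary events go below.
- **Global tie-break** across candidates: CH descending, then the sorted
  dimension pair, then orientation (boundary over the first axis before
  the swapped pass), then q₀ ascending.  With this reduction the result
  is identical across runs and worker counts.
- **Degenerate inputs**: a zero-range axis flags the projection as
  degenerate and it is skipped; non-finite values raise an error naming
  the offending column.  Leaf IDs are assigned depth-first, below-side
  first.

## Label transfer

The pipeline fits a supervised UMAP embedding (2 components,
`target_weight = 0.5`, explicit seed — the embedding is stochastic) on
labeled training events; partially labeled data participate through the
feature term only (label sentinel −1).  The test sample is projected with
the fitted model and clustered in the 2D embedding by mean shift with
full assignment (`cluster_all=True`), the canonical density-mode seeker
that never emits a noise label; the clusterer is pluggable behind a
one-callable contract.  The mean-shift bandwidth is selected by a
stability scan: cluster counts are computed over a geometric ladder of
bandwidths (2%–40% of the embedding's bounding-box diagonal) and the
count stable over the longest stretch of the ladder wins, with ties going
to the coarser clustering.  Cluster IDs are aligned to ground truth by
maximum-total-overlap one-to-one assignment on the contingency table
(Hungarian algorithm); surplus or zero-overlap clusters stay unmatched
and their events count as misclassified.  This alignment is a documented
stand-in for the quadratic-form matching procedure used in the original
gating-automation literature; exact agreement with that procedure is not
claimed.  When the test sample carries no labels, a provisional per-event
truth is derived by 1-nearest-neighbour lookup against the training
events in the embedding before alignment.

The label-quality sanity check computes, per label, the mean intra-label
embedded distance divided by the leave-one-out median of that statistic
across the other labels; a ratio above 3 flags a label that disagrees
with the embedding topology (e.g. one nominal population spanning two
separated blobs).

## Synthetic data

The generators emulate the regimes the method targets: well-separated
Gaussian blob mixtures (exact largest-remainder component allocation so
fixture sizes are deterministic), imbalanced mixtures with a rare
population separable from an abundant mass along a single axis (default
separation 10σ — a clear one-dimensional valley amid uninformative
dimensions), and uniform hypercube samples for the empty-space
demonstration.  They do *not* emulate fluorescence spillover or
compensation, heavy-tailed or zero-inflated count noise, batch effects,
or overlapping populations without any axis-aligned valley; passing tests
therefore show correctness of the algorithm under its stated assumptions,
not performance on raw instrument data (which should be transformed —
e.g. arcsinh — and, for scRNA-seq, PCA-reduced first).

Problem sizes used by the test suite and the acceptance script — 2,000
events for the four-blob recovery, 10,000 for the rare-population regime
(2% rare, 7 dimensions), 2,400 per sample for the 8-component transfer
benchmark, 10⁶ Monte-Carlo draws for the hypercube fraction — were chosen
so each check exercises the full stack at a scale where the expected
behaviour is unambiguous.

## Known limitations

- Only axis-aligned (orthogonal) projections are searched; rotated
  projections are future work.
- Splits are hard; no soft assignments and no merge step, so an early
  erroneous split cannot be repaired.
- Reducing `min_cluster_size` introduces smaller clusters but is not
  guaranteed to be a pure refinement of the coarser clustering.
- The silhouette is computed with Euclidean distance in whatever space
  the labels were produced in, subsampled above 10,000 events.
- FCS files are not read directly; export event tables to CSV/TSV first.
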