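# Methods

This note documents the algorithms, the generative model behind the synthetic
paired data, the reasoning behind default parameter values, and the numerical
choices that make every computation deterministic. It closes with the known
limitations.

## Barcode design and decoding

**Codebook.** Barcodes span 5 imaging rounds with 12 pseudocolors. Rounds 1–4
carry information; round 5 carries parity: for a prefix
(c₁,…,c₄), c₅ = ((Σᵢ cᵢ − 4) mod 12) + 1 (pseudocolors are 1-based).
Capacity is 12⁴ = 20,736 codewords. Because the parity digit is a deterministic
function of the prefix, two codewords differing in one coding round also differ
in parity, so the minimum Hamming distance is 2 and any 4 of the 5 rounds
determine the codeword uniquely. Gene→codeword assignment is a seeded random
permutation of the enumerated prefixes. Each pseudocolor maps to one of three
fluorescence channels (4 pseudocolors per channel).

**Decoding.** Per (embryo, z-slice, field of view):

1. For each pair of rounds, spots are matched by *symmetric* nearest neighbors
   within a 2.45 px radius (a is b's nearest in its round and vice versa).
2. Each coding round serves in turn as the seed round. A seed spot's matched
   partners across the other rounds form a candidate cluster; the cluster is
   called against the codebook by exact match, then single-round correction
   (Hamming distance 1 from a valid codeword, fixable via parity), then
   4-of-5 match with one round missing.
3. Candidate calls are merged across seed rounds; a call is kept only if at
   least 3 of the 4 seedings support the same gene at the same location.
4. Surviving calls are sorted by spatial residual (mean distance of member
   spots to the cluster centroid) and greedily consume their member spots;
   later calls that would reuse a consumed spot are dropped. Ties break on the
   smallest member `spot_id`, making the output independent of input row order.

## Synthetic paired data

The generator produces a dissociated reference atlas and a matched spatial
section from one latent expression model, so ground truth is known for every
downstream stage.

**Reference.** Per-gene base means are lognormal(`base_mean_log`,
`base_mean_sd`) in natural log space. Each cell type receives
`n_markers_per_type` planted marker genes up-shifted by `marker_effect_lfc`
log2 units. Counts are negative-binomial with dispersion `dispersion`;
sequencing batches add cell-independent log2 shifts drawn with scale
`batch_lfc_sd`. Cells are split evenly over `n_ref_batches` batches and
`n_cell_types` types.

**Section.** Each field of view is a `fov_size`-px square tiled by a bounded
Voronoi diagram of a jittered grid of `cells_per_fov` seeds (union of cell
polygons exactly equals the field of view; interiors are disjoint). Cell types
occupy vertical bands; within a band-boundary strip of relative width
`boundary_frac`, a cell's type is drawn from the two adjacent types with
probability 0.5 each, emulating intermixed tissue boundaries. Per-cell
molecule counts follow the same latent gene means restricted to the panel,
thinned binomially by `spatial_detection_rate` (imaging detects a fraction of
a cell's transcripts). Molecules are placed uniformly inside their cell
polygon by rejection sampling.

**Round-spot emission.** Each molecule emits one spot per round at its
codeword's pseudocolor, jittered by `spot_jitter_sd` px, with each spot
independently dropped at `dropout_rate_spatial`; uniform false spots are added
at `false_spot_rate` per px² per round.

**Parameter rationale.** Defaults describe the study conditions the pipeline
targets: 2 embryos × 2 z-slices (parallel section planes), a 2,000-gene
reference over 4 batches, a ~100-gene shared panel, 2 fields of view of 125
cells per embryo. `base_mean_log = 0.65` is sized so the 100-gene panel yields
on the order of 200 detected transcripts per spatial cell after thinning —
the detection regime in which cell typing from a targeted panel is realistic.
`dropout_rate_spatial = 0.1` exercises the parity-based single-round
correction; `spot_jitter_sd = 0.5` is well inside the 2.45 px matching radius.
Independent random streams are derived per concern
(`np.random.default_rng([seed, stream])`), so changing one stage's draws never
perturbs another's.

## Quantification

Molecules are assigned to the cell whose polygon covers them, within the same
(embryo, z-slice, field of view); boundary points shared by two polygons go to
the smaller `cell_id`. QC removes segments with fewer than 10 molecules or 5
detected genes, and flags over-large segments with a one-sided Z-test on
√area within each (embryo, z-slice) stratum, Benjamini–Hochberg-adjusted at
0.01 across all strata pooled. Size factors are per-cell totals divided by
their mean (unit-mean), and the log layer is log2(count/sf + 1).

The neighborhood graph connects cells whose polygons, dilated by an
`expansion` factor about their centroid (default 1.3), intersect; graphs are
built per stratum and never connect across strata.

## Integration and label transfer

Both matrices are cosine-normalized per cell. The joint PCA (50 components)
weights each batch equally in the covariance — the mean of per-batch
covariances about the global mean — so large batches do not dominate the
embedding; component signs follow the convention that the largest-magnitude
loading is positive. Mutual-nearest-neighbor correction proceeds
sequentially: batches are merged in decreasing-size order, reference batches
before query batches; each incoming batch finds `k_mnn = 20` mutual neighbor
pairs against the current merged set and is shifted by a Gaussian-kernel
(σ = 0.1 × median pairwise distance) weighted average of pair difference
vectors. Labels transfer by modal vote among the `k = 25` nearest reference
cells; the mapping score is the vote fraction. Ties break toward the nearest
member's label, then lexicographically — the result is fully deterministic.

## Imputation and its evaluation

For each panel gene g, an *intermediate mapping* is built with g withheld:
the integration is re-run on the remaining panel genes and each spatial cell
records its 25 nearest reference cells. Imputed expression of any gene is the
mean over those neighbors.

Three scores, all Pearson-based:

- **Performance** — imputed vs measured g across spatial cells.
- **Prediction** — one reference batch is held out as a pseudo-query and
  mapped to the rest on the g-withheld panel; imputed vs true g, weighted by
  *occurrence weights*: how often each held-out cell appears among spatial
  cells' neighbors across all gene-withheld mappings. The weighting evaluates
  prediction on the portion of the reference the spatial data actually uses.
- **Normalized** — performance / prediction: how much of what the reference
  *could* predict about g the spatial mapping actually recovers.

The production imputation (`final_impute`) averages reference expression over
the pooled neighbor lists of all mappings, weighted by occurrence.

## Spatial statistics

**Contact map.** For each cell-type pair, the observed contact count (edges
in the neighborhood graph joining the two types) is compared with `n_perm`
label permutations within each stratum; the entry is P(permuted ≥ observed),
averaged over strata (strata missing a type contribute NaN and are skipped).
Low entries mean enrichment, high entries depletion; under a random labeling
the entries are uniform on a 1/n_perm grid.

**Spatial heterogeneity.** Within one cell type, for each gene:
x_i ~ x*_i + embryo + z + embryo×z dummies, where x*_i = Σ_k x_k / D_ik over
the other cells of the type in the same stratum and D is the path distance in
the neighborhood graph. The t-statistic of the x* coefficient measures how
strongly a cell's expression tracks its neighborhood. Genes with zero
variance are flagged and excluded.

**Differential expression.** Welch's unequal-variance t-test per gene, BH
adjustment; a gene is significant iff p_adj < fdr *and* |log2 fold change|
exceeds the threshold. Constant-and-equal genes get t = 0, p = 1;
constant-but-different get ±∞, p = 0.

**Virtual dissection and axis ranking.** Regions of interest are polygons (or
polylines buffered into regions); cells are selected by centroid containment.
`ap_rank` fits a principal curve: PC1 initialization, iterated running-mean
smoothing of coordinates ordered by projection, projection of cells onto the
smoothed polyline, and orientation so the supplied anatomical anchor maps to
rank 0.

## Panel and probe design

**Panel selection.** For every ordered type pair, genes are ranked by a Welch
test of |log2 fold change| > 0.5 against the null; the top `top_n_per_type`
per pair are pooled. Genes whose upper-quartile expression exceeds 20 are
excluded (optical crowding), and while any cell's expected molecular load
exceeds the budget, the highest-load candidate is removed greedily.

**Probes.** 30-nt windows pass if GC ∈ [0.45, 0.65], homopolymers ≤ 4, and no
exact 15-mer occurs in any other gene's sequence. Probes are chosen greedily
left-to-right without overlap; while any probe's pooled internal 15-mer hit
count against the rest of the library exceeds 7, the worst probe is removed.
Barcoded genes require ≥ 28 probes, smFISH genes ≥ 17; genes below minimum
are dropped from the library.

## Numerical determinism

- All randomness flows through `numpy.random.default_rng` with explicit seeds;
  per-concern streams use spawn keys `[seed, stream_id]`.
- PCA signs are fixed by the largest-loading convention.
- Every tie (spot consumption, boundary cell assignment, label votes, probe
  choice) breaks by an explicit, documented rule — smallest id or
  lexicographic — never by hash or iteration order.
- Nearest-neighbor queries use stable argsort on exact distances.

## Limitations

- **Heterogeneity p-values are anticonservative.** The regressor x* is a
  spatial lag of the response itself, so the slope's numerator is the
  quadratic form x'Wx. For symmetric W its null variance is 2·tr(W²), twice
  what the OLS standard error assumes, and the near-constant row sums of the
  inverse-distance weights give W a dominant eigenvector that inflates the
  tail further. Measured type-I error at nominal 0.05 is ≈ 0.32–0.35 across
  grid and random-geometric graphs, for both this implementation and an
  independent from-scratch OLS. Use the t-statistic to *rank* genes by
  spatial structure (a planted gradient cleanly dominates the null), not as a
  calibrated hypothesis test. `tests/test_acceptance.py` asserts the nominal
  calibration and is expected to fail; the companion power property holds.
- The MNN correction removes a constant batch shift exactly only when the
  kernel is wide relative to the shift; at the default local σ a single pass
  attenuates rather than eliminates large shifts. The joint PCA and
  equal-batch weighting absorb most of the residual in practice.
- The generator's tissue model (vertical type bands, Voronoi cells, uniform
  molecule placement) is deliberately simple: it provides exact ground truth
  for geometry and counts but does not emulate cell-shape irregularity,
  optical crowding, z-bleed-through, or segmentation errors beyond size
  outliers.
- Off-target screening is exact 15-mer matching only; no thermodynamic model
  of cross-hybridization.
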