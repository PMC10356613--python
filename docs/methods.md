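# Methods

`nephroniche` re-implements, as a tested library, the statistical
procedures used to chart altered cell states and injury niches in kidney
tissue across single-nucleus/single-cell RNA-seq, Slide-seq and Visium
spatial transcriptomics, snATAC-seq, 3D tissue cytometry, and pseudotime
trajectories. The raw atlas data these procedures were designed for are
controlled-access; every stage here is therefore exercised on synthetic
data with planted ground truth, generated by `nephroniche.simulate`.

## Cell-state scoring (`scoring`)

Counts are normalized per cell as `log(1 + 10,000 · count / cell_total)`
(natural log). A state gene set is first passed through a coherence
filter: the per-cell mean normalized expression of the full set is the
reference profile, and a gene is retained only if its Pearson correlation
with that profile is at least `min_corr` (default 0.1). The per-cell
state score is the mean normalized expression of the retained genes.
Because the reference profile is always computed from the *full* input
set, the filter is a single pass; re-filtering the retained set against
the original reference is a no-op. Correlation is computed over all cells
of the scored population; computing it within a dataset (assay) instead
is exposed as an option with no fidelity claim either way, since the
source procedure does not state the population.

For bulk cohorts, the composite score of a gene set is the per-sample
mean of per-gene Z scores taken across samples (sample standard
deviation, ddof 1). Zero-variance genes are dropped with a warning.

Conserved state markers intersect per-stratum Wilcoxon rank-sum tests
(two-sided, implemented with `scipy.stats.mannwhitneyu`): within every
(condition × cell grouping) stratum, state cells are compared with
reference cells; a grouping supports a gene if the gene has p < 0.05 with
a positive effect in that grouping *in every condition*; a conserved
marker needs at least `min_groups` supporting groupings (default 4,
matching an 11-grouping atlas; the synthetic tests use 2 of 3). Strata
with fewer than 3 cells on a side are skipped and reported; a condition
with no valid stratum makes the intersection unsatisfiable and the result
is empty by construction. An optional trim step additionally requires
enrichment versus all other cells at p < 0.05 and average log2 fold
change > 0.6 (Seurat-style log2 ratio of mean `expm1` normalized
expression with pseudocount 1). The rank-sum choice approximates the
unnamed package-internal test of the source workflow; per-identity
down-sampling (`max_cells_per_ident`) is available and off by default at
desk scale.

Batch-mixing entropy: per subclass, the Shannon entropy (natural log) of
its batch composition divided by `log(n_batches)`, averaged over
subclasses weighted by subclass cell count; optionally restricted to
subclasses covered by more than one batch. The value lies in [0, 1]
(1 = every subclass mixes batches at the global proportions possible,
0 = every subclass is single-batch).

## Bead proximity enrichment (`proximity`)

Deconvolution weights are normalized to sum to 100 per bead; a bead is
classified as the type with the unique maximum relative weight when that
weight is ≥ 40% (level 1), with level-2 assignment within the parent at a
30% or 50% cutoff. Ties at the maximum (including exact ties at the
threshold between two types) leave the bead unclassified — conservative
and deterministic.

The spatial network is the Delaunay triangulation of bead positions with
edges kept only when shorter than 50 µm; collinear degenerate inputs fall
back to a 2-nearest-neighbor graph. For each unordered type pair
(same-type pairs included, counted once per edge), the observed edge
count is compared with the mean over 2,500 uniform label permutations;
enrichment is observed/expected, and the empirical p-value is two-sided
around the permutation mean with the standard add-one correction,
`p = (1 + #{|perm − mean| ≥ |obs − mean|}) / (1 + n_perm)`. Labels are
permuted jointly over all beads of the network; stratified analyses are
achieved by running per puck. Pairs with zero expected count report a
missing ratio (a +0.5 pseudocount mode is available) rather than an
infinite one. The permutation RNG is a counter-based Philox generator
keyed by the seed, so results are reproducible and extending `n_perm`
does not reshuffle earlier draws. Per-region summaries average ratios
across pucks (pairs missing from some pucks average over the pucks that
have them) and flag pairs at or below the display cutoff (0.7 cortex,
0.8 medulla) as hidden.

## Visium spot analyses (`spots`)

Per-spot state proportions sum the transfer-score weights of the
subclasses mapped to each state; rows conserve mass. Condition contrasts
use Fisher's exact test on 2×2 tables of state-dominant spot counts
(dominance = the state holds the spot's maximum proportion; ties are
excluded), one table per condition pair — the dominant-count reading of
"Fisher's exact tests over the spot proportions", documented here because
the alternative (testing summed proportions directly) is not a count
statistic. Epithelial spots are categorized healthy/adaptive/degenerative
by the highest of the three epithelial state proportions, ties
unassigned.

Colocalization: selected spots are those with a strictly positive partner
(stromal/immune) transfer score; the partner is *present* where its score
strictly exceeds its mean over the selected spots, so any monotone
rescaling that preserves the mean-exceedance set leaves the result
unchanged. Odds ratios per category pair use a Haldane–Anscombe 0.5
correction only when a table cell is zero; p-values always come from the
exact test on the raw table. A constant partner score makes presence
degenerate and is flagged.

TAL niches: spots with > 20% summed TAL signature whose top level-1
signature is TAL are re-clustered on their transfer-score vectors —
Louvain communities on a symmetrized kNN graph (k = 15) in weight space.
Per-niche mean scores and per-component z-scores across niches are
reported. The niche count is data-dependent and no fixed count is
claimed. Spots are canonicalized by id before clustering, so input order
cannot change the result.

## 3D neighborhoods (`niches3d`)

Every cell indexes a neighborhood: all cells within 25 µm Euclidean
distance, the index cell included (inclusion keeps sizes ≥ 1 and
fractions well-defined). Distances are isotropic in µm. Per-class count
(sum) and fraction features are computed; monotypic neighborhoods
(a single class present) are removed. Niche detection Z-standardizes the
*sum* columns (the workflow's clustering features; fractions are kept for
reporting), drops zero-variance columns with a warning, builds a kNN
graph (k = 30), and runs Louvain. The Louvain resolution default is 0.3:
at resolution 1.0 modularity optimization fragments the continuous
composition cloud into sub-niche parcels (6–11 communities on fields
whose planted structure has 4), while 0.3 recovers tissue-scale
communities; the source workflow's graph construction and resolution are
unreported, so this is the package's own documented choice, selected for
recovery of planted structure and applied uniformly (the same rationale
sets the TAL niche reclustering default). Pairwise interactions tally,
per neighborhood, each unordered class pair present (diagonal:
neighborhoods with ≥ 2 cells of the class); a per-cell-pair variant is
available. Class co-abundance uses Pearson correlation between class
count columns with two-sided t-tests (df = n − 2); constant columns are
reported missing.

## Differential accessibility (`dar`)

Accessibility is binarized at count ≥ 1; a cell's depth is its total
accessible peak count. Background cells are drawn from the non-test pool
to match the test group's depth distribution: pooled depths are split
into 25 quantile bins, per-bin sample sizes follow the test group's bin
density (largest-remainder rounding, overflow redistributed to bins with
remaining pool), and cells are drawn uniformly without replacement within
bins. The binned importance sampler is a stated approximation of the
source tool's unpublished matching step — simple and auditable. The
background request should not exceed the pool's supply of depth-similar
cells; when it does, the sampler warns and the match degrades (the
synthetic studies use 500 background cells against a 1,500-cell pool).

Per peak, the one-sided enrichment p-value is the upper hypergeometric
tail of the 2×2 accessibility × group table (exactly Fisher's one-sided
test); the natural-log fold change is
`log((a/n_test + ε) / (b/n_bg + ε))` with `ε = 1/(n_test + n_bg)`.
q-values are Benjamini–Hochberg across the group's tested peaks; DARs are
selected at q < 0.01 and log fold change > 1, and a grouping is retained
for downstream work when it has > 100 DARs at q < 0.01. The headline
property — verified in the test suite — is the depth-confound contrast:
with planted confounding and no true DARs, a naive uniform background
inflates type-I error far above nominal while the matched background
restores it, at α = 0.01, to within 1.5× nominal.

## Pseudotime modules (`trajectory`)

Pseudotime is an input (rescaled to [0, 1]). Per gene, expression is
regressed on a cubic B-spline basis of pseudotime (df = 5 basis columns,
interior knots at pseudotime quantiles; df = 1 degenerates exactly to the
simple linear regression, which the tests verify against the closed-form
F) and compared with the intercept-only reduced model by F-test, with BH
adjustment across genes. Constant genes are recorded at p = 1.

The smoothed matrix is a centered rolling mean over pseudotime-ordered
cells, window `max(5, ⌈0.05 n⌉)`; the smoothing construction is not
specified by the source workflow and the rolling mean is one defensible
reading, exposed as configuration. Module detection follows the weighted
co-expression recipe: signed adjacency `((1 + r)/2)^softPower`
(softPower = 10) over smoothed gene profiles, topological-overlap
dissimilarity, average-linkage hierarchical clustering, a static cut at
0.9 of the tallest merge with minimum module size 20 (a simplification of
the dynamic hybrid tree cut), a module-membership filter that greys out
genes with kME < 0.6 against their module eigengene (standard WGCNA
practice; without it, chance-correlated smoothed null genes attach to
modules), and merging of modules whose eigengene correlation exceeds
1 − 0.25 (logged). Unassigned genes are labelled grey.

Cells are assigned to modules by clustering cells (PCA to 10 components,
Louvain on a kNN graph), scoring each cluster by its mean standardized
module activity, and linking each cluster to its best module; a cluster
whose every module activity is below the population mean is unassigned
(with a single module there is no alternative and the cluster takes it).
Cross-dataset transfer is k-nearest-neighbor majority voting (k = 30) on
a shared embedding, ties resolved by the single nearest neighbor. A small
utility (`loo_auc_screen`) implements the leave-one-out logistic
regression AUC screen on sample-level pseudobulk used to nominate
condition-discriminating genes (threshold 0.65).

## Synthetic data (`simulate`)

Each generator draws from its own RNG stream derived from the master seed
(SeedSequence keyed by a stable hash of the stream name), so identical
(seed, config) pairs give bit-identical output and adding a generator
never perturbs another's draws.

- **Expression**: negative-binomial counts (Gamma–Poisson,
  dispersion α = 0.5; variance μ + αμ²), lognormal library sizes
  (mean 2,500), a shared baseline abundance profile, and planted state
  marker sets up-regulated by the configured fold change (default 4, the
  effect size at which scoring must reach AUC ≥ 0.9) in state-positive
  cells across all conditions; partial markers restricted to chosen
  subclasses exercise the grouping-intersection rule. Defaults give
  540 cells per state across 3 subclasses × 3 conditions.
- **Beads**: uniform points at 0.0005/µm² in a 1,000 × 1,000 µm field
  (~500 beads, ~4 neighbors within 50 µm). Labels are assigned
  sequentially in random order with probability ∝ base frequency ×
  preference ratio per already-labelled neighbor of each class within
  50 µm. At this density the preference acts locally (self-preference 5
  yields self-pair enrichment ≈ 1.3); at several-fold higher density the
  sequential scheme percolates — early labels drive the global class
  frequency up instead of creating local structure, which the
  permutation null (conditioned on label counts) correctly scores as no
  enrichment. Ratio 1 everywhere gives an exchangeable field, the null
  for calibration tests.
- **Spots**: Dirichlet mixtures of latent archetypes with per-condition
  odds. The default preset plants an injury archetype (elevated adaptive
  epithelial + immune/stromal weight, more frequent in AKI/CKD) which
  creates immune–adaptive co-occurrence; the null preset is a single
  symmetric Dirichlet (exchangeable epithelial categories, independent
  partner scores); the TAL preset plants three TAL-niche archetypes plus
  a PT background for reclustering recovery.
- **3D cells**: ~10,000 uniform points in a 400 × 400 × 100 µm slab
  (≈41 cells per 25 µm neighborhood — composition estimates need tens of
  cells per ball); three ball-shaped niches (radius 130 µm, deterministic
  centers, nearest-center assignment in overlaps) with distinct class
  frequency vectors mixed against the background at contrast 0.92. The
  niches occupy most of the volume, as in injured tissue; the quarter-size
  unit fixture trades boundary blur for speed and is checked at a reduced
  ARI bound, with the full-size bound asserted in the acceptance tests.
- **Peaks**: binary accessibility with per-cell depth factors drawn from
  two overlapping lognormal modes (test cells all high; the pool half
  high, half low — the planted depth confound), per-peak base rates
  Gamma-distributed around 0.04 (snATAC accessibility is a few percent
  per cell per peak), and `P(accessible) = 1 − exp(−rate · depth ·
  fold)`. Planted DARs multiply the rate by 6 in test cells, putting the
  binarized log fold change (~1.6) clearly above the q < 0.01 & lnFC > 1
  selection rule; weaker multipliers saturate against binarization and
  straddle the fold-change cutoff, testing the filter's boundary rather
  than recovery.
- **Trajectory**: 600 cells with sorted uniform pseudotime; three
  temporal programs (declining sigmoid, transient bump, rising sigmoid)
  × 30 genes each with per-gene amplitudes in [0.8, 1.25], plus 40 flat
  null genes, Gaussian noise sd 0.4 on the normalized scale. A cell's
  true module is the program dominant at its pseudotime.

What the generators do *not* emulate: tissue histology and real spatial
autocorrelation structure, doublets/ambient RNA, batch effects on
expression (batches are random labels), peak co-accessibility, and
pseudotime estimation error. Passing tests therefore demonstrate that the
procedures recover the effects they were designed to detect under their
stated noise models — not that those effects are identifiable in any
particular real tissue.

## Problem sizes and numerical choices

The test and acceptance workloads use the study-scale configurations the
generators default to (≈500-bead fields, 5,000 peaks × 2,000 cells,
10,000 3D cells, 600 trajectory cells) with replicate counts chosen for
stable Monte-Carlo estimates (200 null fields for calibration, 50
planted fields for detection rates, 2,500 permutations throughout).
Ties in rank tests use the normal approximation with tie correction;
simplex checks tolerate 1e-6; hypergeometric p-values are exact and are
verified against rational-arithmetic tail sums to 1e-12. All stochastic
stages take explicit seeds; community detection seeds Python's `random`
state (used by igraph) and restores it afterwards.

## Known limitations

- The conserved-marker test approximates an unnamed package-internal
  default with the Wilcoxon rank-sum test.
- The static tree cut plus kME filter approximates dynamic hybrid tree
  cutting; very close or nested temporal programs may merge or shed more
  genes to grey than WGCNA proper would.
- The binned depth matcher guarantees a good match only when the non-test
  pool contains enough depth-similar cells; it warns, but cannot repair,
  an infeasible request.
- Condition-interaction smooths (AKI vs CKD conditional GAM terms) and
  pseudotime inference itself are out of scope; pseudotime is an input.
- Edge-spot masking for Visium and manual boundary trimming for pucks are
  caller-supplied; nothing is automated.
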