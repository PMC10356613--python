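# nephroniche

Altered cell states and injury niches in kidney tissue: a tested,
reusable implementation of the statistical procedures used to map injury
at single-cell and spatial resolution.

Kidney injury reorganizes tissue locally: adaptive and degenerative
epithelial states appear inside proximal tubule (PT) and thick ascending
limb (TAL) populations, immune and stromal cells accumulate around them,
and chromatin accessibility shifts in the affected lineages. Charting
this requires a set of bespoke statistics that are usually buried in
per-paper analysis scripts. `nephroniche` packages them as a library for
computational biologists working with single-cell, spatial, and 3D
imaging cytometry data:

- **`scoring`** — cell-state gene-set scores with a correlation filter
  (retain gene *g* iff Pearson *r*(*g*, mean profile of the set) ≥ 0.1 on
  log-normalized data), bulk composite scores (per-sample mean of
  per-gene *Z*), conserved-marker intersection across conditions and
  cell groupings (Wilcoxon rank-sum, *p* < 0.05 in every condition, ≥ *k*
  groupings), and normalized batch-mixing entropy weighted by subclass
  size.
- **`proximity`** — Slide-seq bead classification from deconvolution
  weights (≥ 40% relative weight at level 1; 30%/50% at level 2) and
  cell-type proximity enrichment on a Delaunay network (edges < 50 µm):
  observed/expected edge counts against 2,500 label permutations, with
  per-region puck averaging.
- **`spots`** — Visium-style analyses on transfer scores: per-spot state
  proportions, Fisher tests of state-dominant spots across conditions,
  healthy/adaptive/degenerative categorization, mean-exceedance
  colocalization odds ratios, and re-clustering of >20%-TAL spots into
  niches with per-component z-scores.
- **`niches3d`** — 3D tissue-cytometry neighborhoods (25 µm radius),
  per-class sum/fraction features, monotypic removal, Z-standardized
  Louvain niche communities, pairwise interaction tallies, and Pearson
  class-abundance correlations.
- **`dar`** — differentially accessible chromatin regions with
  depth-matched background sampling and exact one-sided hypergeometric
  (Fisher) tests, BH correction, and the *q* < 0.01 & ln FC > 1 filter.
- **`trajectory`** — pseudotime association by cubic-spline regression
  versus an intercept-only model (F-test, BH), rolling-mean smoothing,
  WGCNA-style module detection (softPower 10, min module size 20),
  module-to-cell assignment, and kNN majority-vote module transfer.
- **`simulate`** — generators for every input modality with planted
  ground truth (state signatures, adjacency preferences, spot archetype
  mixtures, 3D niche communities, depth-confounded peaks, temporal gene
  modules), so the whole pipeline is testable end to end without any
  controlled-access download.

## Worked example

Plant a spatial self-affinity (class A prefers A neighbors, ratio 5) in a
synthetic bead field, then ask the permutation test to find it; plant 200
differentially accessible peaks under a depth confound, then recover them
against a depth-matched background:

```python
import numpy as np
from nephroniche import simulate as sim, proximity, dar

pref = ((5.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
beads, truth = sim.simulate_beads(sim.BeadConfig(seed=0, preference=pref))
net = proximity.build_network(beads, max_dist=50)
enr = proximity.proximity_enrichment(net, beads["label"], n_perm=2500, seed=0)
print(f"{len(beads)} beads, {len(net)} edges")
print(enr.round(3).to_string(index=False))

pk, pk_truth = sim.simulate_peaks(sim.PeakConfig(seed=0))
test = (pk.obs["group"] == "test").to_numpy()
bg = dar.match_background(pk.obs["depth"], test, n_background=500, seed=0)
res = dar.test_dars(pk.X, np.where(test)[0], bg, peak_names=list(pk.var_names))
hits = dar.filter_dars(res, q_max=0.01, lfc_min=1.0)
planted = {pk.var_names[i] for i in pk_truth.dar_peaks}
print(f"{len(hits)} DARs at q<0.01 & lnFC>1; "
      f"recall {len(set(hits) & planted) / len(planted):.2f}")
```

Output:

```
503 beads, 794 edges
type_a type_b  observed  expected  ratio     p  n_perm
     A      A       409   308.869  1.324 0.000    2500
     A      B       136   191.264  0.711 0.000    2500
     A      C       113   182.148  0.620 0.000    2500
     B      B        40    29.332  1.364 0.031    2500
     B      C        65    56.048  1.160 0.217    2500
     C      C        31    26.338  1.177 0.337    2500
197 DARs at q<0.01 & lnFC>1; recall 0.98
```

The planted A–A affinity shows up as enrichment 1.32 (409 observed A–A
edges against 308.9 expected under label permutation, empirical
p < 1/2501), with the complementary A–B and A–C depletion; the B and C
pairs, which carry no planted structure, sit near 1. The DAR stage
recovers 98% of the planted peaks with the *q* and fold-change filters
applied against a depth-matched background — with a naive uniform
background, the depth confound would flood the list with false
positives (the test suite measures that contrast directly).

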