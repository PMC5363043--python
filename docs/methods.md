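# Methods

This note records the models, statistics, parameter choices and numerical
conventions behind `miccnet`, and what the synthetic benchmark does and does
not establish.

## Problem setting

Rare multi-organ diseases yield many small expression cohorts on different
platforms and tissues that cannot be pooled sample-wise. The package
implements a consensus strategy: cluster each dataset into co-expression
modules independently, connect modules from different datasets when their
gene overlap exceeds random expectation, and read conserved biology off the
community structure of the resulting *module overlap network*. Genes carried
by disease-enriched communities in every dataset of a tissue form tissue
consensus sets, whose cross-tissue union is then interpreted inside
tissue-specific functional-interaction networks (hubs, bridges, differential
wiring between tissues).

## Preprocessing

Probe rows sharing a gene ID are collapsed to the row mean (NaN-ignoring),
then each gene is median-centred. Genes with more than 20 % missing entries
are removed (boundary inclusive: exactly 20 % is retained). Order of
operations is collapse → filter → centre. Imputation is out of scope, so all
downstream moments and correlations are pairwise-complete. Per-gene
z-scores use the sample standard deviation (n−1 denominator); zero-variance
genes are dropped with a warning rather than raising, so degenerate probes
cannot halt a run.

## Co-expression modules

Signed adjacency `a_ij = ((1 + r_ij)/2)^β` with soft-thresholding power
β = 12 maps anti-correlated pairs near zero. The topological overlap
dissimilarity of this adjacency feeds average-linkage hierarchical
clustering. The tree is cut **statically at dissimilarity 0.8**
(`cut_height`, exposed): on the TOM scale unrelated pairs concentrate near
1 and co-module pairs sit well below, so a fixed cut between the two
regimes is stable. A quantile-of-merge-heights rule was evaluated and
rejected — when most genes are unclustered background, high height
quantiles land at the dendrogram root and merge everything. Clusters below
`min_module_size = 20` are dropped (genes become "unassigned"); modules
whose eigengenes correlate above `1 − merge_height = 0.85` are merged
iteratively, highest pair first.

The module eigengene is the first right-singular vector of the
gene-standardized module submatrix, unit norm, sign-oriented so that its
correlation with the module's mean standardized profile is non-negative
(the sign convention is a package choice; only relative directions matter).

Phenotype association per module eigengene: two-sided Mann–Whitney U for
two-class categorical phenotypes, Spearman test for continuous ones,
Bonferroni correction across the modules tested within each phenotype.
Mann–Whitney is exact when both groups have ≤ 10 tie-free observations,
otherwise the normal approximation with tie and continuity correction.
Direction is the sign of the median shift toward the lexicographically
larger level (e.g. "disease" > "control").

Differential expression uses a permutation d-statistic
`d = (m₁ − m₂)/(s + s₀)` with pooled standard error `s` and fudge factor
`s₀ = median(s)` held fixed across permutations — a deliberate
simplification of the original quantile-optimized fudge factor. Per-gene
q-values are the median permutation count of `|d*| ≥ |d|` over the observed
count, capped at 1 and made monotone in `|d|`. When the label arrangements
number at most `n_permutations`, all are enumerated.

## Module overlap network

For modules `C_i`, `C_j` from two datasets sharing `N` measured genes,

    W_ij = (|C_i ∩ C_j| / N) · log2( N · |C_i ∩ C_j| / (|C_i| |C_j|) )

is the (i, j) term of the mutual information (bits) between the two module
partitions: positive/negative/zero for overlap above/below/at random
expectation, with `0·log 0 := 0`. Summing `W_ij` over all label pairs of a
dataset pair equals the partition mutual information exactly; this identity
is the module's primary test oracle. Base-2 logs are a convention — the
base rescales all scores without changing signs or rankings.

Unassigned genes are excluded from modules but stay in the universe `N`
(configurable). The default edge-retention policy keeps `W_ij > 0` edges
whose one-sided hypergeometric overlap p-value passes Bonferroni correction
over all module pairs of that dataset pair at α = 0.05; a `positive_only`
policy is also provided and is always a supergraph of the default.
Significance of whole-pair MI is assessed by permuting one partition's gene
labels over the shared universe; both the raw exceedance p and the add-one
version are reported.

## Communities and annotation

Top-level communities: Clauset–Newman–Moore greedy modularity maximization
on the weighted overlap network (igraph, nodes fed in sorted order for
determinism), each connected component handled independently; labels are
numerals by decreasing size. Bottom-level: within each top-level community,
spin-glass (Potts) optimization with simulated annealing — spins ≤ 10,
γ = 1, geometric schedule T₀ = 1, cooling 0.99, stop at 10⁻³, 5 restarts
keeping the best modularity — with letters by decreasing sub-community
size. The hierarchy nests by construction. Modularity significance comes
from shuffling community labels (sizes preserved) and comparing weighted
modularity.

Community phenotype enrichment is a two-sided Fisher exact test of
community membership against the module association flag (either
direction), Bonferroni-corrected across communities within each phenotype.
Two-sided was chosen over one-sided as the conservative default.

Pathway annotation works on *edge gene sets* `E_ij = C_i ∩ C_j` (over the
pair's shared universe): per pathway `P`, Jaccard `J(E, P)` is computed for
every edge, and within-community edges are compared to all other edges by
two-sided Mann–Whitney, Bonferroni across pathways within the community.
Annotation runs at either hierarchy level; sub-communities resolve finer
processes that dilute each other at the top level.

## Consensus genes

Disease communities are selected by rule (top-level Bonferroni p ≤ α for
any phenotype, keeping bottom-level children that contain
phenotype-increased modules) with a manual override, since the analogous
selection in practice is analyst-driven. Per dataset, the union of its
selected modules' genes; per tissue, the intersection of those unions
across the tissue's datasets (a single-dataset tissue contributes its union
directly — intersections are over the tissue's common measured universe);
the cross-tissue union is the axis consensus. Validation: consensus genes'
Pearson correlation to their module eigengene versus non-consensus genes
(two-sided Mann–Whitney, per dataset), and one-sided Fisher enrichment of
consensus membership among permutation-DE up-regulated genes (q < 0.05,
d > 0).

## Functional-network query and differential networks

Querying: induced subgraph on the query genes, edges below the interaction
probability threshold (default 0.5) pruned, largest connected component
kept (ties break toward the smallest lexicographic node ID), spin-glass
functional modules with the shared engine. No re-pruning is applied after
differential subtraction.

Hubs: per module of ≥ 5 genes, the top `ceil(0.05 · module size)` genes
(minimum 1) by weighted within-module degree, ties by gene ID. Bridges:
genes with participation coefficient `P = 1 − Σ_s (k_s/k)² ≥ 0.5` over
module-wise weighted degrees and total weighted degree at least the
component median. Both thresholds are package defaults — the underlying
notions are qualitative — and are exposed in the API. `P` is bounded by
`1 − 1/m` for `m` modules. Module annotation is a one-sided hypergeometric
test against a GMT collection over the component's gene universe (default),
Benjamini–Hochberg within module.

Differential adjacency between a focal network and (comparator, baseline):
`A_diff = max(A_focal − max(A_comp, A_base), 0)` entrywise over the common
largest-component nodes, missing edges read as 0. Consequences used as test
properties: the same edge cannot be positive in both directions of
comparison, and raising any comparator weight never raises the differential
weight. The single-comparator variant sets comparator = baseline.
Community weight classification permutes node labels of the adjacency
(simultaneous row/column permutation — preserving the weight multiset and
degree structure) 1000 times and labels each community "more"/"less"/"none"
against the central 95 % null band (the band is a package choice; only the
three-way outcome is prescribed).

## Gene-set scoring

A set's score in a sample is the mean z-score of its measured member
genes. Sets with platform coverage below 0.5 are flagged, not scored.
Group comparison is a two-sided Mann–Whitney per set; raw p-values are
reported by default (mirroring common practice for small targeted panels),
with an optional Benjamini–Hochberg column.

## Synthetic data: what it emulates and what it does not

The compendium generator plants rank-one modules (eigengene × loadings
uniform in [0.5, 1]) plus Gaussian noise (σ = 0.3 by default) in datasets
of 40 samples on partially overlapping universes (85 % of a 1200-gene
master list, sampled without replacement). The disease axis consists of 3
shared processes of 30 genes whose eigengenes shift by 2 SD in disease
samples (half of each cohort); each dataset carries the axis at a different
module granularity (whole axis, halves, per-process — cycling), the way
real cohorts split a common signal differently, which is what fuses the
axis into one overlap-network community with sub-structure. Three neutral
shared processes (no disease shift) provide conserved non-disease
communities, and the remaining planted modules are dataset-specific.
Disease effects act on the eigengene, not per gene, so the planted signal
is a coherent module shift.

The network triple plants 3 dense backbone communities (within-weight 0.9)
common to tissue A, tissue B and global networks, 2 extra communities per
tissue elevated only in that tissue, a background of weight 0.1, connector
edges (8 % of outside pairs, weights 0.55–0.75, identical in all three
networks so they cancel in the differential adjacency but keep pruned
query graphs connected), and edge-weight noise σ = 0.05 clipped to [0, 1]
(clipping fraction logged).

These generators reproduce the *structure* the method exploits — planted
partitions, shared processes, tissue-specific wiring — not microarray
reality: no probe effects, batch effects, heavy-tailed noise,
sample-dependent missingness, or correlated background genes. Passing the
recovery suite therefore shows the pipeline's inferential machinery is
correct and calibrated under its own model, not that real-data findings are
automatic.

## Problem sizes and determinism

Default synthetic sizes (1200-gene master list, 4 datasets × 40 samples,
150-gene network triples) were chosen so that a full end-to-end run takes
roughly a second and multi-seed recovery studies run in minutes on one
core. All stochastic components consume NumPy `SeedSequence`-derived
generators; igraph's annealer is driven by a seeded Python RNG per call, so
every result, including spin-glass partitions, is reproducible bit-for-bit
under a fixed seed. The pipeline runner derives per-stage child seeds from
the global seed so stages can be rerun in isolation.

## Known limitations

* The static tree cut assumes a bimodal TOM-dissimilarity distribution; on
  data where module and background dissimilarities overlap heavily, the
  dynamic tree-cut family will outperform it.
* The overlap-edge hypergeometric threshold tests marginal overlaps; it
  does not model the dependence between module pairs of the same dataset
  pair.
* The SAM-style fudge factor `s₀ = median(s)` is coarser than the original
  quantile optimization and can over-shrink when most genes are null.
* Hub/bridge thresholds are conventions; sensitivity analyses over
  `top_fraction` and `min_participation` are the user's responsibility.
* Fisher-based community enrichment needs communities of nontrivial size;
  with very few datasets the test is underpowered at the top level.
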