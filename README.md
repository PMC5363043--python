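# miccnet

Multi-network consensus analysis of multi-tissue gene expression.

`miccnet` is for researchers who have several small expression cohorts —
different tissues, platforms and gene universes — and want to know which
transcriptional processes are *shared* across them and how those processes
behave inside tissue-specific functional interaction networks. It was built
around the study design of multi-organ fibrotic disease (systemic sclerosis
skin, lung, esophagus and blood cohorts), but every stage is generic.

## What it computes

1. **Co-expression modules per dataset.** Signed weighted network
   (`a_ij = ((1 + r_ij)/2)^β`, β = 12), topological-overlap dissimilarity,
   average-linkage clustering with a static tree cut, eigengene merging.
   Each module is summarized by its eigengene (first principal component)
   and tested against sample phenotypes (Mann–Whitney U / Spearman,
   Bonferroni per phenotype).

2. **Module overlap network (mutual-information consensus clustering).**
   For modules `C_i`, `C_j` from different datasets sharing `N` genes,

   ```
   W_ij = (|C_i ∩ C_j| / N) · log2( N·|C_i ∩ C_j| / (|C_i|·|C_j|) )
   ```

   is the (i, j) term of the mutual information between the two module
   partitions (bits): positive exactly when the modules overlap more than
   expected at random. Positive, hypergeometric-significant overlaps become
   edges of a multipartite module graph; partition-level MI significance is
   assessed by gene-label permutation.

3. **Hierarchical communities.** Greedy modularity maximization gives large
   top-level communities ("1", "2", …); spin-glass optimization inside each
   gives sub-communities ("1a", "1b", …). Communities are tested for
   enrichment of phenotype-associated modules (Fisher exact, Bonferroni)
   and annotated with pathways via the Jaccard similarity of *edge gene
   sets* `E_ij = C_i ∩ C_j` to GMT gene sets (Mann–Whitney within vs
   outside the community).

4. **Tissue consensus genes.** For disease-enriched communities: per
   dataset the union of its member modules' genes, per tissue the
   intersection across that tissue's datasets, and the cross-tissue union —
   a consensus disease signature validated by eigengene-centrality and
   DE-enrichment tests.

5. **Functional-network interrogation.** Query tissue-specific probability
   networks with the consensus genes (prune edges < 0.5, largest component,
   spin-glass functional modules, hypergeometric annotation), identify hub
   genes (top weighted within-module degree) and bridge genes (high
   participation coefficient), and contrast tissues with the differential
   adjacency `A_diff = max(A_focal − max(A_comp, A_base), 0)`, including a
   permutation classifier for community weight excess.

6. **Gene-set z-score summaries.** Per-sample average z-scores of
   user-supplied gene sets (e.g. macrophage activation-state modules) with
   Mann–Whitney group comparisons.

A synthetic-data module generates multi-dataset compendia and network
triples with planted ground truth (shared disease processes, neutral shared
processes, tissue-specific communities), so the whole pipeline is testable
end to end.

## Worked example

```python
import miccnet as mn
from miccnet.micc import attach_phenotype_flags

datasets, truth = mn.generate_compendium(mn.CompendiumSpec(seed=1))
parts = []
for ds in datasets:
    part = mn.detect_modules(ds)
    mn.associate_phenotypes(part, ds.phenotypes.drop(columns=["dataset_id", "tissue"]))
    parts.append(part)
    print(f"{ds.dataset_id} ({ds.tissue}): {len(part.modules)} modules")

net = mn.build_overlap_network(parts)
attach_phenotype_flags(net)
assignment = mn.detect_bottom_level(net, mn.detect_top_level(net), seed=1)
attrs = {n: dict(net.graph.nodes[n]) for n in net.graph.nodes}
enrich = mn.phenotype_enrichment(assignment, attrs)
selected = mn.select_disease_communities(enrich, assignment, attrs)
cons = mn.derive_tissue_consensus(parts, assignment, selected)
print(f"selected sub-communities: {selected}")
print(f"axis consensus: {len(cons.union_set)} genes; "
      f"recovered {len(cons.union_set & truth.axis_genes)} of {len(truth.axis_genes)} planted")
```

prints

```
DS1 (skin): 7 modules
DS2 (lung): 8 modules
DS3 (esophagus): 8 modules
DS4 (pbmc): 8 modules
selected sub-communities: ['1a', '1b']
axis consensus: 101 genes; recovered 90 of 90 planted
```

The four cohorts carry a planted disease axis (3 shared processes, 90
genes) at different module granularities. The overlap network fuses those
modules into one community whose sub-communities are selected by
disease-module enrichment (Fisher Bonferroni p ≈ 6 × 10⁻⁶ on this run); the
consensus set algebra then recovers all 90 planted axis genes (plus 11
co-clustered background genes — precision 0.89, recall 1.0).

## Command line

```bash
miccnet simulate compendium --config cfg.yaml --out data/
miccnet simulate networks --out nets/ --seed 3
miccnet pipeline validate --config run.yaml
miccnet pipeline run --config run.yaml
miccnet netquery --network nets/network_lung.tsv --genes axis.txt --prune 0.5 --out q/
miccnet diffnet --focal lung.tsv --comparator skin.tsv --baseline global.tsv --genes axis.txt --out d/
miccnet score --z zmat.tsv --gmt modules.gmt --groups pheno.tsv --group-col disease_status --out s/
```

All tabular I/O is TSV (expression matrices, phenotype tables, edge lists,
module maps) and GMT for gene sets; `pipeline run` writes a JSON manifest
with per-stage parameters, outputs and checksums, and a rerun with the same
config is checksum-identical.

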