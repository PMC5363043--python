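"""Tissue consensus gene sets from disease-enriched overlap-network communities.

For the communities enriched in disease-associated modules, each dataset
contributes the union of its member modules' genes; datasets from the same
tissue are intersected, giving one consensus gene set per tissue; the union
across tissues is the cross-tissue disease-axis consensus used to query
functional networks.  Two validation checks accompany the derivation:
consensus genes should sit closer to their module eigengenes than
non-consensus genes (Mann–Whitney on Pearson correlations), and should be
enriched among genes called up-regulated by the permutation d-statistic
(one-sided Fisher).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr

from .coexpression import DEResult, ModulePartition, mann_whitney_two_sided
from .communities import CommunityAssignment, Node

logger = logging.getLogger(__name__)


@dataclass
class ConsensusGeneSet:
    """Per-tissue consensus genes and their cross-tissue union."""

    per_tissue: dict[str, set[str]]
    union_set: set[str] = field(default_factory=set)
    source_communities: list[str] = field(default_factory=list)
    selected_nodes: list[Node] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.union_set):
            tissues = sorted(t for t, s in self.per_tissue.items() if gene in s)
            rows.append({"gene": gene, "tissues": ";".join(tissues), "in_union": True})
        return pd.DataFrame(rows)


def select_disease_communities(
    enrichment_table: pd.DataFrame,
    assignment: CommunityAssignment,
    node_attributes: dict[Node, dict],
    alpha: float = 0.05,
    override: list[str] | None = None,
) -> list[str]:
    """Pick the disease-enriched communities whose modules feed the consensus.

    Top-level communities with Bonferroni p ≤ ``alpha`` for at least one
    phenotype are selected; their bottom-level children are kept only when
    they contain at least one phenotype-increased module.  ``override``
    short-circuits the rule with an analyst-chosen list of bottom-level
    labels.
    """
    if override is not None:
        return list(override)
    sig_top = sorted(
        set(
            enrichment_table.loc[enrichment_table["bonferroni_p"] <= alpha, "community"]
            .astype(str)
        )
    )
    if not sig_top:
        logger.warning("no community passes enrichment at alpha=%g", alpha)
        return []
    selected: list[str] = []
    for bottom_label in sorted(set(assignment.bottom.values())):
        top_of = bottom_label.rstrip("abcdefghijklmnopqrstuvwxyz")
        if top_of not in sig_top:
            continue
        members = assignment.bottom_members(bottom_label)
        has_increased = any(
            any(k.startswith("increased_") and v for k, v in node_attributes.get(n, {}).items())
            for n in members
        )
        if has_increased:
            selected.append(bottom_label)
    return selected


def derive_tissue_consensus(
    partitions: list[ModulePartition],
    assignment: CommunityAssignment,
    selected_communities: list[str],
    tissue_map: dict[str, str] | None = None,
) -> ConsensusGeneSet:
    """Set algebra of the consensus: per dataset the union of its selected
    modules' genes, per tissue the intersection of those unions across the
    tissue's datasets (a single-dataset tissue contributes its union
    directly), and the union of tissue sets across tissues."""
    if tissue_map is None:
        tissue_map = {p.dataset_id: p.tissue for p in partitions}
    selected = set(selected_communities)
    selected_nodes = [n for n, lab in assignment.bottom.items() if lab in selected]
    by_dataset: dict[str, set[str]] = {}
    for dataset_id, module in selected_nodes:
        part = next(p for p in partitions if p.dataset_id == dataset_id)
        by_dataset.setdefault(dataset_id, set()).update(part.modules[module])
    per_tissue: dict[str, set[str]] = {}
    for dataset_id, genes in by_dataset.items():
        tissue = tissue_map[dataset_id]
        if tissue in per_tissue:
            per_tissue[tissue] &= genes
        else:
            per_tissue[tissue] = set(genes)
    for tissue, genes in per_tissue.items():
        if not genes:
            logger.warning("tissue %r: datasets share no selected genes", tissue)
    union_set = set().union(*per_tissue.values()) if per_tissue else set()
    return ConsensusGeneSet(per_tissue, union_set, sorted(selected), selected_nodes)


def consensus_centrality_test(
    partitions: list[ModulePartition],
    consensus: ConsensusGeneSet,
    datasets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per dataset: do consensus genes correlate more strongly with their
    module eigengene than non-consensus genes in the selected modules?

    ``datasets`` maps dataset_id to its expression matrix.  Returns one row
    per testable dataset with median correlations and the two-sided
    Mann–Whitney p.
    """
    rows = []
    selected_by_dataset: dict[str, list[str]] = {}
    for dataset_id, module in consensus.selected_nodes:
        selected_by_dataset.setdefault(dataset_id, []).append(module)
    for part in partitions:
        if part.dataset_id not in selected_by_dataset:
            continue
        matrix = datasets[part.dataset_id]
        cors_cons, cors_other = [], []
        for module in selected_by_dataset[part.dataset_id]:
            eig = part.eigengenes[module].to_numpy()
            for gene in part.modules[module]:
                r = pearsonr(matrix.loc[gene].to_numpy(dtype=float), eig)[0]
                (cors_cons if gene in consensus.union_set else cors_other).append(r)
        if len(cors_cons) < 2 or len(cors_other) < 2:
            logger.info("dataset %r: degenerate consensus split; skipped", part.dataset_id)
            continue
        stat, p = mann_whitney_two_sided(np.array(cors_cons), np.array(cors_other))
        rows.append(
            {
                "dataset_id": part.dataset_id,
                "n_consensus": len(cors_cons),
                "n_other": len(cors_other),
                "median_consensus_r": float(np.median(cors_cons)),
                "median_other_r": float(np.median(cors_other)),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def consensus_de_enrichment(
    consensus: ConsensusGeneSet | set[str], de_result: DEResult, fdr: float = 0.05
) -> dict:
    """One-sided Fisher enrichment of consensus genes among DE-up genes.

    The 2x2 table crosses consensus membership with (q < ``fdr`` and d > 0)
    over the DE result's gene universe.
    """
    cons = consensus.union_set if isinstance(consensus, ConsensusGeneSet) else set(consensus)
    universe = set(de_result.genes)
    cons &= universe
    if not cons:
        raise ValueError("consensus set shares no genes with the DE universe")
    up = set(de_result.significant_up(fdr))
    a = len(cons & up)
    b = len(cons - up)
    c = len(up - cons)
    d = len(universe) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": float(odds),
        "p_value": float(p),
    }
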