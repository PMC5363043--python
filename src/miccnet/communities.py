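"""Hierarchical community detection and annotation on the module overlap network.

Top-level communities come from greedy modularity maximization over the
weighted overlap network (large, diffuse clusters, labeled "1", "2", ...).
Within each top-level community, spin-glass optimization finds tighter
bottom-level sub-communities (labeled "1a", "1b", ... by decreasing size).
Community structure is validated by a label-permutation modularity test;
communities are then characterized by (a) Fisher-exact enrichment of
phenotype-associated modules and (b) pathway annotation of their edge gene
sets — the gene intersections carried by overlap-network edges — via
within- versus outside-community Jaccard similarity compared by
Mann–Whitney U.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._engine import greedy_modularity, spinglass_communities, weighted_modularity
from .coexpression import mann_whitney_two_sided
from .micc import ModuleOverlapNetwork

logger = logging.getLogger(__name__)

Node = tuple[str, str]


@dataclass
class CommunityAssignment:
    """Hierarchical community labels: numerals on top, numeral+letter below."""

    top: dict[Node, str]
    bottom: dict[Node, str] = field(default_factory=dict)
    modularity_top: float = float("nan")
    modularity_bottom: float = float("nan")

    def top_members(self, label: str) -> list[Node]:
        return [n for n, lab in self.top.items() if lab == label]

    def bottom_members(self, label: str) -> list[Node]:
        return [n for n, lab in self.bottom.items() if lab == label]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_id": n[0],
                "module": n[1],
                "top_label": self.top[n],
                "bottom_label": self.bottom.get(n, ""),
            }
            for n in self.top
        ]
        return pd.DataFrame(rows)


def _sub_letters(k: int) -> list[str]:
    letters = string.ascii_lowercase
    out = []
    for i in range(k):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def detect_top_level(network: ModuleOverlapNetwork) -> CommunityAssignment:
    """Greedy-modularity top-level communities, labeled by decreasing size."""
    graph = network.graph
    if graph.number_of_edges() == 0:
        logger.warning("overlap network has no edges; every node is its own community")
    raw, q = greedy_modularity(graph)
    groups: dict[int, list[Node]] = {}
    for n, lab in raw.items():
        groups.setdefault(lab, []).append(n)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), repr(sorted(g, key=repr))))
    top = {}
    for i, members in enumerate(ordered, start=1):
        for n in members:
            top[n] = str(i)
    return CommunityAssignment(top, modularity_top=q)


def detect_bottom_level(
    network: ModuleOverlapNetwork,
    top_assignment: CommunityAssignment,
    max_communities: int = 10,
    seed: int = 0,
) -> CommunityAssignment:
    """Spin-glass sub-communities within each top-level community.

    Letters are assigned by decreasing sub-community size; top-level
    communities below 3 nodes become a single sub-community without
    annealing.  The hierarchy nests by construction: the optimizer only ever
    sees the induced subgraph of one top-level community.
    """
    graph = network.graph
    bottom: dict[Node, str] = {}
    top_labels = sorted(set(top_assignment.top.values()), key=lambda s: (len(s), s))
    for t_i, t_label in enumerate(top_labels):
        members = top_assignment.top_members(t_label)
        sub = graph.subgraph(members)
        if len(members) < 3:
            for n in members:
                bottom[n] = t_label + "a"
            continue
        labels, _ = spinglass_communities(
            sub, max_communities=max_communities, seed=seed * 101 + t_i
        )
        groups: dict[int, list[Node]] = {}
        for n, lab in labels.items():
            groups.setdefault(lab, []).append(n)
        ordered = sorted(groups.values(), key=lambda g: (-len(g), repr(sorted(g, key=repr))))
        for letter, grp in zip(_sub_letters(len(ordered)), ordered):
            for n in grp:
                bottom[n] = t_label + letter
    lab_index = {lab: i for i, lab in enumerate(sorted(set(bottom.values())))}
    q_bottom = weighted_modularity(graph, {n: lab_index[lab] for n, lab in bottom.items()})
    return CommunityAssignment(
        dict(top_assignment.top),
        bottom,
        modularity_top=top_assignment.modularity_top,
        modularity_bottom=q_bottom,
    )


def modularity_permutation_test(
    network: ModuleOverlapNetwork,
    assignment: CommunityAssignment,
    n_permutations: int = 1000,
    seed: int | None = None,
    level: str = "top",
) -> dict:
    """Permutation test of modularity: shuffle node community labels
    (community sizes preserved) and compare the null Q distribution with the
    observed Q."""
    graph = network.graph
    labels = assignment.top if level == "top" else assignment.bottom
    nodes = sorted(graph.nodes, key=repr)
    lab_list = np.array([labels[n] for n in nodes])
    observed = weighted_modularity(graph, dict(zip(nodes, lab_list)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = weighted_modularity(graph, dict(zip(nodes, rng.permutation(lab_list))))
    return {
        "observed_Q": observed,
        "null_Q": null,
        "p_raw": float((null >= observed).mean()),
    }


def phenotype_enrichment(
    assignment: CommunityAssignment,
    node_attributes: dict[Node, dict],
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher-exact enrichment of phenotype-associated modules per top community.

    For each (top-level community, phenotype): a 2x2 table of community
    membership against the module's association flag (counting modules
    associated in either direction), tested two-sided and
    Bonferroni-corrected across communities within the phenotype.
    """
    if phenotypes is None:
        phenotypes = sorted(
            {
                k.removeprefix("associated_")
                for attrs in node_attributes.values()
                for k in attrs
                if k.startswith("associated_")
            }
        )
    nodes = list(assignment.top)
    rows = []
    top_labels = sorted(set(assignment.top.values()), key=lambda s: (len(s), s))
    for pheno in phenotypes:
        flags = {
            n: bool(node_attributes.get(n, {}).get(f"associated_{pheno}", False))
            for n in nodes
        }
        n_assoc = sum(flags.values())
        if n_assoc == 0:
            logger.info("phenotype %r has no associated modules", pheno)
        per_pheno = []
        for label in top_labels:
            members = set(assignment.top_members(label))
            if not members:
                logger.warning("community %r is empty; skipped", label)
                continue
            a = sum(1 for n in members if flags[n])
            b = len(members) - a
            c = n_assoc - a
            d = len(nodes) - len(members) - c
            if n_assoc == 0:
                stat, p = float("nan"), 1.0
            else:
                stat, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            per_pheno.append(
                {
                    "community": label,
                    "phenotype": pheno,
                    "n_in_assoc": a,
                    "n_in_total": len(members),
                    "odds_ratio": float(stat),
                    "raw_p": float(p),
                }
            )
        for row in per_pheno:
            row["bonferroni_p"] = min(1.0, row["raw_p"] * len(per_pheno))
        rows.extend(per_pheno)
    return pd.DataFrame(rows)


def edge_gene_sets(network: ModuleOverlapNetwork) -> dict[tuple[Node, Node], set[str]]:
    """Per overlap-network edge, the intersection of the two endpoint modules
    over the dataset pair's shared universe."""
    out: dict[tuple[Node, Node], set[str]] = {}
    for u, v in network.graph.edges:
        shared = set(network.partitions[u[0]].universe) & set(
            network.partitions[v[0]].universe
        )
        genes = network.module_genes(u) & network.module_genes(v) & shared
        if not genes:
            logger.warning("edge %r–%r has an empty gene set", u, v)
        key = (u, v) if repr(u) <= repr(v) else (v, u)
        out[key] = genes
    return out


def jaccard(a: set[str], b: set[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def annotate_communities(
    edge_sets: dict[tuple[Node, Node], set[str]],
    assignment: CommunityAssignment,
    pathways: dict[str, dict],
    level: str = "top",
) -> pd.DataFrame:
    """Pathway annotation per community via edge gene sets.

    For every pathway, the Jaccard similarity between each edge gene set and
    the pathway is computed; within-community edges (both endpoints in the
    community) are compared against all other edges with a two-sided
    Mann–Whitney U, Bonferroni-corrected across pathways within each
    community.  Direction is the sign of the within-minus-outside median
    (mean when the medians tie).  ``level`` selects top-level communities or
    bottom-level sub-communities, which resolve finer processes.
    """
    edges = sorted(edge_sets, key=repr)
    universe = set().union(*edge_sets.values()) if edge_sets else set()
    rows = []
    labels_map = assignment.top if level == "top" else assignment.bottom
    members_of = (
        assignment.top_members if level == "top" else assignment.bottom_members
    )
    top_labels = sorted(set(labels_map.values()), key=lambda s: (len(s), s))
    for label in top_labels:
        members = set(members_of(label))
        inside = [e for e in edges if e[0] in members and e[1] in members]
        outside = [e for e in edges if e not in set(inside)]
        if not inside or not outside:
            logger.info("community %r: no within/outside edge split; skipped", label)
            continue
        per_comm = []
        for name in sorted(pathways):
            genes = set(pathways[name]["genes"])
            if not genes & universe:
                logger.info("pathway %r has no genes in any edge set; skipped", name)
                continue
            j_in = np.array([jaccard(edge_sets[e], genes) for e in inside])
            j_out = np.array([jaccard(edge_sets[e], genes) for e in outside])
            stat, p = mann_whitney_two_sided(j_in, j_out)
            shift = float(np.median(j_in) - np.median(j_out))
            if shift == 0.0:
                shift = float(np.mean(j_in) - np.mean(j_out))
            per_comm.append(
                {
                    "community": label,
                    "pathway": name,
                    "within_median_J": float(np.median(j_in)),
                    "outside_median_J": float(np.median(j_out)),
                    "statistic": stat,
                    "raw_p": p,
                    "direction": float(np.sign(shift)),
                }
            )
        for row in per_comm:
            row["bonferroni_p"] = min(1.0, row["raw_p"] * len(per_comm))
        rows.extend(per_comm)
    return pd.DataFrame(rows)
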