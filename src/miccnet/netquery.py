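"""Querying tissue-specific functional networks with a gene set.

A functional network is an undirected gene graph whose edge weights are
interaction probabilities in [0, 1].  Querying extracts the induced
subgraph on the query genes, prunes low-probability edges (default < 0.5),
keeps the largest connected component and partitions it into functional
modules with the shared spin-glass engine.  Hubs are the highest
weighted-within-module-degree genes of each module; bridges are genes whose
weighted degree is split across modules (high participation coefficient)
with enough total degree to matter.  Modules are annotated against a GMT
gene-set collection by one-sided hypergeometric enrichment with
Benjamini–Hochberg correction within each module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._engine import spinglass_communities
from . import io

logger = logging.getLogger(__name__)


@dataclass
class FunctionalNetwork:
    """Undirected weighted gene graph; weights are interaction probabilities."""

    graph: nx.Graph
    tissue: str = ""

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge ({u!r},{v!r}) weight {w} outside [0,1]")

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str, float]], tissue: str = ""
    ) -> "FunctionalNetwork":
        g = nx.Graph()
        g.add_weighted_edges_from(edges)
        return cls(g, tissue)

    @classmethod
    def from_tsv(cls, path: str | Path, tissue: str = "") -> "FunctionalNetwork":
        return cls.from_edges(io.read_edge_list(path), tissue)

    def to_tsv(self, path: str | Path) -> None:
        edges = sorted(
            (min(u, v), max(u, v), float(w)) for u, v, w in self.graph.edges(data="weight")
        )
        io.write_edge_list(edges, path)


@dataclass
class QueryResult:
    """Outcome of querying a functional network with a gene set."""

    subnetwork: FunctionalNetwork
    component: nx.Graph
    functional_modules: dict[str, int] = field(default_factory=dict)
    hubs: dict[int, list[str]] = field(default_factory=dict)
    bridges: list[str] = field(default_factory=list)
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def component_nodes(self) -> set[str]:
        return set(self.component.nodes)


def query_network(
    network: FunctionalNetwork,
    query_genes: list[str],
    prune_below: float = 0.5,
    seed: int = 0,
    max_communities: int = 10,
) -> QueryResult:
    """Induced subgraph on the query genes, probability-pruned, restricted to
    the largest connected component, with spin-glass functional modules.

    Component size ties break toward the component containing the smallest
    lexicographic node ID.
    """
    present = [g for g in query_genes if g in network.graph]
    if len(present) < 2:
        missing = sorted(set(query_genes) - set(network.graph))
        raise ValueError(
            f"fewer than 2 query genes found in network; missing (first 10): {missing[:10]}"
        )
    sub = nx.Graph()
    sub.add_nodes_from(present)
    for u, v, w in network.graph.subgraph(present).edges(data="weight"):
        if w >= prune_below:
            sub.add_edge(u, v, weight=float(w))
    components = list(nx.connected_components(sub))
    largest = sorted(components, key=lambda c: (-len(c), min(c)))[0]
    component = nx.Graph(sub.subgraph(largest))
    modules, _ = spinglass_communities(component, max_communities=max_communities, seed=seed)
    return QueryResult(
        FunctionalNetwork(sub, network.tissue), component, dict(modules)
    )


def find_hubs(result: QueryResult, top_fraction: float = 0.05) -> dict[int, list[str]]:
    """Per functional module, the top-weighted-degree genes.

    Ranks genes by weighted within-module degree and keeps the top
    ``ceil(top_fraction * module size)`` (at least 1).  Ties break by gene ID.
    Modules below 5 genes yield no hubs.
    """
    graph = result.component
    by_module: dict[int, list[str]] = {}
    for gene, m in result.functional_modules.items():
        by_module.setdefault(m, []).append(gene)
    hubs: dict[int, list[str]] = {}
    for m, genes in sorted(by_module.items()):
        if len(genes) < 5:
            continue
        members = set(genes)
        degree = {
            g: sum(
                w for _, v, w in graph.edges(g, data="weight") if v in members
            )
            for g in genes
        }
        ranked = sorted(genes, key=lambda g: (-degree[g], g))
        k = max(1, math.ceil(top_fraction * len(genes)))
        hubs[m] = ranked[:k]
    result.hubs = hubs
    return hubs


def participation_coefficient(
    graph: nx.Graph, gene: str, modules: dict[str, int]
) -> float:
    """P = 1 − Σ_s (k_s / k)² over the gene's weighted degree to each module."""
    per_module: dict[int, float] = {}
    total = 0.0
    for _, v, w in graph.edges(gene, data="weight"):
        per_module[modules[v]] = per_module.get(modules[v], 0.0) + w
        total += w
    if total <= 0:
        return 0.0
    return 1.0 - sum((k / total) ** 2 for k in per_module.values())


def find_bridges(result: QueryResult, min_participation: float = 0.5) -> list[str]:
    """Genes whose connections are split across modules: participation
    coefficient ≥ ``min_participation`` and weighted degree at least the
    component median."""
    graph = result.component
    modules = result.functional_modules
    if len(set(modules.values())) < 2:
        raise ValueError("bridge detection needs at least 2 functional modules")
    degree = {
        g: sum(w for _, _, w in graph.edges(g, data="weight")) for g in graph.nodes
    }
    median_degree = float(np.median(list(degree.values()))) if degree else 0.0
    bridges = sorted(
        g
        for g in graph.nodes
        if participation_coefficient(graph, g, modules) >= min_participation
        and degree[g] >= median_degree
    )
    result.bridges = bridges
    return bridges


def annotate_modules(
    result: QueryResult,
    genesets: dict[str, dict],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each functional module against
    each gene set, Benjamini–Hochberg corrected within module.

    The default enrichment universe is the query component's gene set.
    """
    if universe is None:
        universe = result.component_nodes
    universe = set(universe)
    if not universe >= result.component_nodes:
        raise ValueError("universe must contain all functional-module genes")
    by_module: dict[int, set[str]] = {}
    for gene, m in result.functional_modules.items():
        by_module.setdefault(m, set()).add(gene)
    rows = []
    for m, members in sorted(by_module.items()):
        per_module = []
        for name in sorted(genesets):
            genes = set(genesets[name]["genes"]) & universe
            if not genes:
                logger.info("gene set %r has no genes in universe; skipped", name)
                continue
            overlap = len(members & genes)
            p = float(
                hypergeom.sf(overlap - 1, len(universe), len(genes), len(members))
            )
            per_module.append(
                {
                    "module": m,
                    "gene_set": name,
                    "overlap": overlap,
                    "set_size": len(genes),
                    "module_size": len(members),
                    "raw_p": p,
                }
            )
        if per_module:
            _, q, _, _ = multipletests(
                [r["raw_p"] for r in per_module], alpha=alpha, method="fdr_bh"
            )
            for r, qv in zip(per_module, q):
                r["bh_q"] = float(qv)
        rows.extend(per_module)
    result.annotations = pd.DataFrame(rows)
    return result.annotations
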