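"""Differential network analysis between tissue-specific functional networks.

The differential network of a focal tissue against a comparator tissue and a
global baseline keeps, per gene pair, only the weight excess of the focal
network over the larger of the two others:

    A_diff = max(A_focal − max(A_comparator, A_baseline), 0)

so its edges are interactions that are distinctly stronger in the focal
tissue.  Missing edges count as weight 0.  The single-comparator variant
(subtract only the baseline) is the same operation with comparator set to
the baseline network.  Communities in the differential network come from
the shared spin-glass engine on its largest connected component, and each
community's within-weight is classified against a node-label permutation
null as carrying more, less, or no different weight than random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._engine import spinglass_communities
from .netquery import FunctionalNetwork, QueryResult

logger = logging.getLogger(__name__)


@dataclass
class DifferentialNetwork:
    """Nonnegative differential adjacency over a stated common node set."""

    nodes: list[str]
    adjacency: np.ndarray
    provenance: tuple[str, str, str] = ("", "", "")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        idx = np.argwhere(np.triu(self.adjacency, k=1) > 0)
        for i, j in idx:
            g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.adjacency[i, j]))
        return g

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), w) for u, v, w in self.graph().edges(data="weight")
        )


def common_nodes(result_a: QueryResult, result_b: QueryResult) -> list[str]:
    """Intersection of two query results' largest-component node sets."""
    shared = result_a.component_nodes & result_b.component_nodes
    if not shared:
        raise ValueError("query results share no component nodes")
    return sorted(shared)


def _weight_matrix(network: FunctionalNetwork, nodes: list[str]) -> np.ndarray:
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, w in network.graph.edges(data="weight"):
        if u in index and v in index:
            a[index[u], index[v]] = a[index[v], index[u]] = float(w)
    return a


def differential_adjacency(
    focal: FunctionalNetwork,
    comparator: FunctionalNetwork,
    baseline: FunctionalNetwork,
    nodes: list[str],
) -> DifferentialNetwork:
    """Entrywise max(A_focal − max(A_comparator, A_baseline), 0) over nodes."""
    af = _weight_matrix(focal, nodes)
    ac = _weight_matrix(comparator, nodes)
    ab = _weight_matrix(baseline, nodes)
    diff = np.maximum(af - np.maximum(ac, ab), 0.0)
    np.fill_diagonal(diff, 0.0)
    return DifferentialNetwork(
        list(nodes), diff, (focal.tissue, comparator.tissue, baseline.tissue)
    )


def differential_communities(
    diff_network: DifferentialNetwork, seed: int = 0, max_communities: int = 10
) -> dict[str, int]:
    """Spin-glass modules on the largest connected component of the positive
    differential edges; empty when the differential network has no edges."""
    g = diff_network.graph()
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        logger.warning("differential network has no positive edges")
        return {}
    largest = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))[0]
    component = g.subgraph(largest)
    labels, _ = spinglass_communities(component, max_communities=max_communities, seed=seed)
    return dict(labels)


def community_weight_permutation(
    network: FunctionalNetwork | DifferentialNetwork,
    modules: dict[str, int],
    n_permutations: int = 1000,
    seed: int | None = None,
    band: float = 0.95,
) -> dict[int, str]:
    """Classify each community's within-weight against a permutation null.

    The null permutes node labels of the adjacency (simultaneous row/column
    permutation, preserving the weight multiset and degree structure) and
    recomputes each community's total within-community weight.  A community
    is labeled ``"more"`` above the (1+band)/2 null quantile, ``"less"``
    below the (1−band)/2 quantile, else ``"none"``.
    """
    nodes = sorted(modules)
    if isinstance(network, DifferentialNetwork):
        index = {n: i for i, n in enumerate(network.nodes)}
        sel = [index[n] for n in nodes]
        a = network.adjacency[np.ix_(sel, sel)]
    else:
        a = _weight_matrix(network, nodes)
    labels = np.array([modules[n] for n in nodes])
    unique = sorted(set(labels.tolist()))
    masks = {m: labels == m for m in unique}

    def within_weights(mat: np.ndarray) -> dict[int, float]:
        return {m: float(mat[np.ix_(masks[m], masks[m])].sum()) / 2.0 for m in unique}

    observed = within_weights(a)
    rng = np.random.default_rng(seed)
    null = {m: np.empty(n_permutations) for m in unique}
    n = len(nodes)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        ap = a[np.ix_(perm, perm)]
        for m, w in within_weights(ap).items():
            null[m][i] = w
    lo, hi = (1.0 - band) / 2.0, (1.0 + band) / 2.0
    out: dict[int, str] = {}
    for m in unique:
        low = float(np.quantile(null[m], lo))
        high = float(np.quantile(null[m], hi))
        if observed[m] > high:
            out[m] = "more"
        elif observed[m] < low:
            out[m] = "less"
        else:
            out[m] = "none"
    return out
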