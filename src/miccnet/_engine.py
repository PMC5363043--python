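"""Shared community-detection engine (igraph-backed) used by several stages.

Greedy modularity maximization and Potts-model spin-glass optimization both
run on weighted undirected graphs.  Nodes are fed to igraph in sorted order
so that the greedy agglomeration is deterministic; the stochastic spin-glass
anneal is made reproducible by seeding igraph's Python random generator per
call and keeping the best-modularity result over several restarts.
"""

from __future__ import annotations

import random
from typing import Hashable

import igraph
import networkx as nx

SPINGLASS_DEFAULTS = dict(start_temp=1.0, stop_temp=1e-3, cool_fact=0.99, gamma=1.0)


def _to_igraph(graph: nx.Graph) -> tuple[igraph.Graph, list[Hashable]]:
    nodes = sorted(graph.nodes, key=repr)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [float(graph.edges[u, v].get("weight", 1.0)) for u, v in graph.edges]
    g = igraph.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def greedy_modularity(graph: nx.Graph) -> tuple[dict[Hashable, int], float]:
    """Fast-greedy modularity maximization; returns labels and achieved Q.

    Disconnected graphs are handled natively (each component agglomerated
    independently).  An edgeless graph yields singleton communities, Q = 0.
    """
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes, key=repr))}, 0.0
    g, nodes = _to_igraph(graph)
    clustering = g.community_fastgreedy(weights="weight").as_clustering()
    labels = {nodes[i]: int(m) for i, m in enumerate(clustering.membership)}
    return labels, float(g.modularity(clustering.membership, weights="weight"))


def spinglass_communities(
    graph: nx.Graph,
    max_communities: int = 10,
    seed: int = 0,
    restarts: int = 5,
) -> tuple[dict[Hashable, int], float]:
    """Spin-glass (Potts model) community detection with simulated annealing.

    Runs on each connected component of ≥3 nodes independently (the
    optimizer requires connectivity); smaller components become single
    communities.  Keeps the best-modularity result over ``restarts``
    seeded restarts.  Returns node → community label and the weighted
    modularity of the full labeling.
    """
    labels: dict[Hashable, int] = {}
    offset = 0
    for comp_i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: (-len(c), repr(sorted(c, key=repr))))
    ):
        sub = graph.subgraph(comp)
        if len(comp) < 3 or sub.number_of_edges() == 0:
            for n in comp:
                labels[n] = offset
            offset += 1
            continue
        g, nodes = _to_igraph(sub)
        best_membership, best_q = None, -float("inf")
        for r in range(restarts):
            igraph.set_random_number_generator(random.Random(seed * 1000 + comp_i * 37 + r))
            cl = g.community_spinglass(
                weights="weight", spins=max_communities, **SPINGLASS_DEFAULTS
            )
            q = g.modularity(cl.membership, weights="weight")
            if q > best_q:
                best_q, best_membership = q, list(cl.membership)
        igraph.set_random_number_generator(None)
        for i, m in enumerate(best_membership):
            labels[nodes[i]] = offset + int(m)
        offset += max(best_membership) + 1
    q_total = weighted_modularity(graph, labels)
    return labels, q_total


def weighted_modularity(graph: nx.Graph, labels: dict[Hashable, int]) -> float:
    """Newman weighted modularity of a labeling (0 for an edgeless graph)."""
    if graph.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set] = {}
    for n, lab in labels.items():
        groups.setdefault(lab, set()).add(n)
    return float(
        nx.algorithms.community.modularity(graph, list(groups.values()), weight="weight")
    )
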