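"""Mutual-information consensus clustering: the module overlap network.

Modules detected independently in different datasets have no a priori
relationship.  For a pair of modules C_i (dataset A) and C_j (dataset B)
sharing a measured-gene universe of size N, the overlap score

    W_ij = (n_ij / N) * log2(N * n_ij / (n_i * n_j)),   n_ij = |C_i ∩ C_j|

is the (i, j) term of the mutual information between the two partitions:
positive when the modules overlap more than expected at random, negative
when less, zero at independence (and by convention when n_ij = 0).  Summing
W_ij over all module pairs of a dataset pair recovers the partition mutual
information exactly — the identity that anchors this module's tests.

The module overlap network keeps, per dataset pair, the module pairs whose
overlap is positive and (under the default policy) significant by a
Bonferroni-corrected one-sided hypergeometric test.  Genes carrying the
"unassigned" label are excluded from modules but remain in the universe N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .coexpression import UNASSIGNED, ModulePartition

logger = logging.getLogger(__name__)


def overlap_score(n_ij: int, n_i: int, n_j: int, N: int) -> float:
    """Mutual-information overlap term of one module pair, in bits."""
    if not (0 <= n_ij <= min(n_i, n_j) and max(n_i, n_j) <= N and n_i >= 1 and n_j >= 1):
        raise ValueError(
            f"invalid overlap counts: n_ij={n_ij}, n_i={n_i}, n_j={n_j}, N={N}"
        )
    if n_ij == 0:
        return 0.0
    return (n_ij / N) * np.log2(N * n_ij / (n_i * n_j))


def _mi_bits(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """MI in bits of two integer label vectors (joint contingency via bincount)."""
    n = codes_a.size
    ka = int(codes_a.max()) + 1
    kb = int(codes_b.max()) + 1
    joint = np.bincount(codes_a * kb + codes_b, minlength=ka * kb).astype(float)
    nz = joint > 0
    ca = np.bincount(codes_a, minlength=ka).astype(float)
    cb = np.bincount(codes_b, minlength=kb).astype(float)
    outer = np.repeat(ca, kb) * np.tile(cb, ka)
    j = joint[nz]
    return float(np.sum((j / n) * np.log2(n * j / outer[nz])))


def partition_mutual_information(
    partition_a: dict[str, str], partition_b: dict[str, str], shared_genes: list[str]
) -> float:
    """Mutual information (bits) of two module-label assignments over shared genes."""
    if not shared_genes:
        raise ValueError("shared gene universe is empty")
    la = np.array([partition_a[g] for g in shared_genes])
    lb = np.array([partition_b[g] for g in shared_genes])
    return _mi_bits(
        np.unique(la, return_inverse=True)[1], np.unique(lb, return_inverse=True)[1]
    )


@dataclass
class ModuleOverlapNetwork:
    """Multipartite weighted graph over (dataset_id, module_label) nodes.

    ``graph`` edges carry the retained overlap scores; ``shared_universe_sizes``
    records N per dataset pair; node attributes hold per-module phenotype
    association flags when supplied.
    """

    graph: nx.Graph
    shared_universe_sizes: dict[frozenset, int] = field(default_factory=dict)
    partitions: dict[str, ModulePartition] = field(default_factory=dict)

    @property
    def nodes(self) -> list[tuple[str, str]]:
        return list(self.graph.nodes)

    def module_genes(self, node: tuple[str, str]) -> set[str]:
        dataset_id, label = node
        return set(self.partitions[dataset_id].modules[label])


def build_overlap_network(
    partitions: list[ModulePartition],
    threshold_policy: str = "positive+hypergeometric",
    alpha: float = 0.05,
    include_unassigned_in_universe: bool = True,
) -> ModuleOverlapNetwork:
    """Compute all cross-dataset overlap scores and keep the significant edges.

    Policies: ``"positive+hypergeometric"`` keeps edges with W > 0 whose
    one-sided hypergeometric overlap p-value passes Bonferroni correction over
    all module pairs of that dataset pair at ``alpha``; ``"positive_only"``
    keeps every W > 0 edge.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    if threshold_policy not in {"positive+hypergeometric", "positive_only"}:
        raise ValueError(f"unknown threshold_policy {threshold_policy!r}")
    graph = nx.Graph()
    universe_sizes: dict[frozenset, int] = {}
    for part in partitions:
        for label in part.modules:
            graph.add_node(
                (part.dataset_id, label),
                dataset_id=part.dataset_id,
                module=label,
                tissue=part.tissue,
            )
    for pa, pb in combinations(partitions, 2):
        ua, ub = set(pa.universe), set(pb.universe)
        shared = ua & ub
        if not include_unassigned_in_universe:
            shared = {
                g for g in shared
                if pa.assignments[g] != UNASSIGNED or pb.assignments[g] != UNASSIGNED
            }
        if not shared:
            logger.warning(
                "datasets %r and %r share no genes; pair skipped",
                pa.dataset_id, pb.dataset_id,
            )
            continue
        N = len(shared)
        universe_sizes[frozenset({pa.dataset_id, pb.dataset_id})] = N
        mods_a = {m: set(g) & shared for m, g in pa.modules.items()}
        mods_b = {m: set(g) & shared for m, g in pb.modules.items()}
        mods_a = {m: g for m, g in mods_a.items() if g}
        mods_b = {m: g for m, g in mods_b.items() if g}
        n_pairs = len(mods_a) * len(mods_b)
        for ma, ga in mods_a.items():
            for mb, gb in mods_b.items():
                n_ij = len(ga & gb)
                w = overlap_score(n_ij, len(ga), len(gb), N)
                if w <= 0:
                    continue
                if threshold_policy == "positive+hypergeometric":
                    # P[X >= n_ij], X ~ Hypergeom(N, n_i, n_j)
                    p = float(hypergeom.sf(n_ij - 1, N, len(ga), len(gb)))
                    if p * n_pairs > alpha:
                        continue
                graph.add_edge(
                    (pa.dataset_id, ma), (pb.dataset_id, mb), weight=float(w), n_ij=n_ij
                )
    return ModuleOverlapNetwork(
        graph, universe_sizes, {p.dataset_id: p for p in partitions}
    )


def attach_phenotype_flags(
    network: ModuleOverlapNetwork, alpha: float = 0.05
) -> None:
    """Flag each overlap-network node with its module's phenotype associations.

    A node gets ``associated_<phenotype> = True`` when the module's
    Bonferroni-corrected p is at most ``alpha``, and ``increased_<phenotype>``
    when additionally the association direction is positive.
    """
    for node in network.graph.nodes:
        dataset_id, label = node
        part = network.partitions[dataset_id]
        for (module, pheno), res in part.association_results.items():
            if module != label:
                continue
            sig = res["bonferroni_p"] <= alpha
            network.graph.nodes[node][f"associated_{pheno}"] = bool(sig)
            network.graph.nodes[node][f"increased_{pheno}"] = bool(
                sig and res["direction"] > 0
            )


def mi_permutation_test(
    partition_a: ModulePartition | dict[str, str],
    partition_b: ModulePartition | dict[str, str],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict:
    """Permutation test of the mutual information between two partitions.

    The null permutes the gene labels of one partition over the shared
    universe.  Returns the observed MI, the null draws, the raw exceedance
    p-value and the add-one corrected version (1 + #null ≥ obs)/(1 + B).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be ≥ 1")
    a = partition_a.assignments if isinstance(partition_a, ModulePartition) else partition_a
    b = partition_b.assignments if isinstance(partition_b, ModulePartition) else partition_b
    shared = sorted(set(a) & set(b))
    if len(shared) < 10:
        raise ValueError(f"shared universe has {len(shared)} genes; need ≥ 10")
    observed = partition_mutual_information(a, b, shared)
    rng = np.random.default_rng(seed)
    codes_a = np.unique(np.array([a[g] for g in shared]), return_inverse=True)[1]
    codes_b = np.unique(np.array([b[g] for g in shared]), return_inverse=True)[1]
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _mi_bits(codes_a, rng.permutation(codes_b))
    count = int((null >= observed).sum())
    return {
        "observed_mi": observed,
        "null_mis": null,
        "p_raw": count / n_permutations,
        "p_add_one": (1 + count) / (1 + n_permutations),
    }
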