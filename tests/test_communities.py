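"""Hierarchical community detection, modularity testing, Fisher enrichment
and edge-gene-set pathway annotation, with brute-force oracles for the
max-modularity split and the Fisher exact test."""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pytest
from scipy.stats import fisher_exact
from sklearn.metrics import adjusted_rand_score

import miccnet as mn
from miccnet._engine import spinglass_communities, weighted_modularity
from miccnet.communities import jaccard
from miccnet.micc import ModuleOverlapNetwork


def as_overlap_network(graph):
    return ModuleOverlapNetwork(graph)


def two_clique_graph():
    g = nx.Graph()
    left = [("A", f"M{i}") for i in range(4)]
    right = [("B", f"M{i}") for i in range(4)]
    for part in (left, right):
        for u, v in itertools.combinations(part, 2):
            g.add_edge(u, v, weight=1.0)
    g.add_edge(left[0], right[0], weight=1.0)
    return g, left, right


def set_partitions(items):
    """All set partitions of a small collection (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] + [first]] + partial[i + 1:]
        yield [[first]] + partial


def brute_force_best_modularity(graph):
    nodes = list(graph.nodes)
    best_q, best = -np.inf, None
    for partition in set_partitions(nodes):
        labels = {n: i for i, grp in enumerate(partition) for n in grp}
        q = weighted_modularity(graph, labels)
        if q > best_q:
            best_q, best = q, partition
    return best_q, best


def brute_force_fisher_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-12)
    )


class TestTopLevel:
    def test_two_cliques_recovered_and_match_brute_force(self):
        g, left, right = two_clique_graph()
        result = mn.detect_top_level(as_overlap_network(g))
        groups = {}
        for n, lab in result.top.items():
            groups.setdefault(lab, set()).add(n)
        assert set(map(frozenset, groups.values())) == {
            frozenset(left), frozenset(right)
        }
        best_q, best = brute_force_best_modularity(g)
        assert set(map(frozenset, best)) == {frozenset(left), frozenset(right)}
        assert result.modularity_top == pytest.approx(best_q)

    def test_uniform_complete_graph_single_community(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: ("A", f"M{i}") for i in range(6)})
        nx.set_edge_attributes(g, 1.0, "weight")
        result = mn.detect_top_level(as_overlap_network(g))
        assert len(set(result.top.values())) == 1

    def test_modularity_at_least_singletons(self, overlap_network):
        result = mn.detect_top_level(overlap_network)
        singletons = {n: i for i, n in enumerate(overlap_network.graph.nodes)}
        assert result.modularity_top >= weighted_modularity(
            overlap_network.graph, singletons
        )

    def test_edgeless_network_all_singletons(self, caplog):
        g = nx.Graph()
        g.add_nodes_from([("A", "M1"), ("B", "M1")])
        with caplog.at_level("WARNING"):
            result = mn.detect_top_level(as_overlap_network(g))
        assert len(set(result.top.values())) == 2
        assert result.modularity_top == 0.0


class TestBottomLevel:
    def planted_two_block(self, rng):
        g = nx.Graph()
        blocks = [[("A", f"M{i}") for i in range(8)],
                  [("B", f"M{i}") for i in range(8)]]
        for block in blocks:
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v, weight=1.0)
        for u in blocks[0]:
            for v in blocks[1]:
                if rng.random() < 0.1:
                    g.add_edge(u, v, weight=0.05)
        g.add_edge(blocks[0][0], blocks[1][0], weight=0.05)
        return g, blocks

    def test_planted_blocks_recovered_within_top_community(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g, blocks = self.planted_two_block(rng)
            net = as_overlap_network(g)
            top = mn.CommunityAssignment({n: "1" for n in g.nodes})
            full = mn.detect_bottom_level(net, top, seed=seed)
            truth = [0] * 8 + [1] * 8
            nodes = blocks[0] + blocks[1]
            found = [full.bottom[n] for n in nodes]
            assert adjusted_rand_score(truth, found) == pytest.approx(1.0)

    def test_uniform_clique_single_subcommunity(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: ("A", f"M{i}") for i in range(6)})
        nx.set_edge_attributes(g, 1.0, "weight")
        net = as_overlap_network(g)
        top = mn.CommunityAssignment({n: "1" for n in g.nodes})
        full = mn.detect_bottom_level(net, top, seed=0)
        assert set(full.bottom.values()) == {"1a"}

    def test_seeded_reproducibility(self, overlap_network):
        top = mn.detect_top_level(overlap_network)
        a = mn.detect_bottom_level(overlap_network, top, seed=42)
        b = mn.detect_bottom_level(overlap_network, top, seed=42)
        assert a.bottom == b.bottom

    def test_hierarchy_nests(self, assignment):
        parent = {}
        for node, bottom in assignment.bottom.items():
            top = assignment.top[node]
            assert bottom.startswith(top)
            prev = parent.setdefault(bottom, top)
            assert prev == top

    def test_labels_cover_all_nodes(self, overlap_network, assignment):
        nodes = set(overlap_network.graph.nodes)
        assert set(assignment.top) == nodes
        assert set(assignment.bottom) == nodes


class TestModularityPermutation:
    def test_single_community_gives_p_one(self):
        g, _, _ = two_clique_graph()
        net = as_overlap_network(g)
        single = mn.CommunityAssignment({n: "1" for n in g.nodes})
        res = mn.modularity_permutation_test(net, single, n_permutations=50, seed=0)
        assert res["p_raw"] == 1.0

    def test_planted_structure_highly_significant(self):
        g = nx.Graph()
        left = [("A", f"M{i}") for i in range(8)]
        right = [("B", f"M{i}") for i in range(8)]
        for part in (left, right):
            for u, v in itertools.combinations(part, 2):
                g.add_edge(u, v, weight=1.0)
        g.add_edge(left[0], right[0], weight=1.0)
        labels = {n: ("1" if n in set(left) else "2") for n in g.nodes}
        res = mn.modularity_permutation_test(
            as_overlap_network(g), mn.CommunityAssignment(labels),
            n_permutations=500, seed=0,
        )
        assert res["p_raw"] == 0.0

    def test_random_labels_on_random_graph_not_significant(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(20, 0.3, seed=seed)
            g = nx.relabel_nodes(g, {i: ("A", f"M{i}") for i in range(20)})
            nx.set_edge_attributes(g, 1.0, "weight")
            labels = {n: str(rng.integers(0, 4)) for n in g.nodes}
            res = mn.modularity_permutation_test(
                as_overlap_network(g), mn.CommunityAssignment(labels),
                n_permutations=99, seed=seed,
            )
            rejections += res["p_raw"] <= 0.05
        assert rejections / n_seeds <= 0.10


class TestFisherEnrichment:
    @pytest.mark.parametrize(
        "table",
        [
            [[8, 2], [10, 80]],
            [[5, 0], [0, 5]],
            [[0, 5], [5, 0]],
            [[3, 4], [2, 3]],
            [[1, 1], [1, 1]],
        ],
    )
    def test_fisher_matches_brute_force(self, table):
        _, p = fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(brute_force_fisher_two_sided(table), abs=1e-12)

    def test_fisher_all_small_tables_match_oracle(self):
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        if a + b + c + d == 0 or a + b + c + d > 12:
                            continue
                        _, p = fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(
                            brute_force_fisher_two_sided([[a, b], [c, d]]), abs=1e-12
                        )

    def test_extreme_community_minimal_p(self):
        assignment = mn.CommunityAssignment(
            {("A", f"M{i}"): ("1" if i < 5 else "2") for i in range(30)}
        )
        attrs = {("A", f"M{i}"): {"associated_x": i < 5} for i in range(30)}
        table = mn.phenotype_enrichment(assignment, attrs)
        row = table[(table.community == "1") & (table.phenotype == "x")].iloc[0]
        assert row.raw_p == pytest.approx(
            brute_force_fisher_two_sided([[5, 0], [0, 25]]), abs=1e-12
        )

    def test_no_associated_modules_reports_p_one(self):
        assignment = mn.CommunityAssignment(
            {("A", f"M{i}"): ("1" if i < 3 else "2") for i in range(6)}
        )
        attrs = {("A", f"M{i}"): {"associated_x": False} for i in range(6)}
        table = mn.phenotype_enrichment(assignment, attrs)
        assert (table.raw_p == 1.0).all()

    def test_disease_community_enriched_on_reference_run(self, enrichment):
        sig = enrichment[
            (enrichment.phenotype == "disease_status")
            & (enrichment.bonferroni_p <= 0.05)
        ]
        assert len(sig) == 1


class TestEdgeGeneSets:
    def test_fixture_intersections(self):
        import pandas as pd
        from miccnet.coexpression import ModulePartition

        filler = {g: "unassigned" for g in "FGHIJ"}
        pa = ModulePartition("A", {g: "M1" for g in "ABCD"} | {"E": "unassigned"} | filler)
        pb = ModulePartition("B", {g: "M1" for g in "CDE"} | {g: "unassigned" for g in "AB"} | filler)
        net = mn.build_overlap_network([pa, pb], threshold_policy="positive_only")
        sets = mn.edge_gene_sets(net)
        assert sets[(("A", "M1"), ("B", "M1"))] == {"C", "D"}

    def test_reference_edge_sets_subset_of_modules(self, overlap_network):
        sets = mn.edge_gene_sets(overlap_network)
        for (u, v), genes in sets.items():
            assert genes <= overlap_network.module_genes(u)
            assert genes <= overlap_network.module_genes(v)
            assert len(genes) >= 1


class TestAnnotateCommunities:
    @pytest.mark.parametrize(
        "e,p,expected",
        [({"a", "b"}, {"a", "b"}, 1.0), ({"a"}, {"b"}, 0.0), (set(range(10)), set(range(5, 20)), 0.25)],
    )
    def test_jaccard_bounds_and_arithmetic(self, e, p, expected):
        assert jaccard(e, p) == pytest.approx(expected)

    def test_planted_process_annotated(self, overlap_network, assignment, compendium):
        _, truth = compendium
        sets = mn.edge_gene_sets(overlap_network)
        gmt = mn.generate_genesets(truth, decoys=3, seed=1)
        table = mn.annotate_communities(sets, assignment, gmt)
        hits = table[
            table.pathway.str.startswith("NP")
            & (table.bonferroni_p < 0.05)
            & (table.within_median_J > table.outside_median_J)
        ]
        assert set(hits.pathway) == set(truth.neutral_genes)

    def test_invariant_to_pathway_order(self, overlap_network, assignment, compendium):
        _, truth = compendium
        sets = mn.edge_gene_sets(overlap_network)
        gmt = mn.generate_genesets(truth, decoys=2, seed=2)
        reversed_gmt = dict(reversed(list(gmt.items())))
        a = mn.annotate_communities(sets, assignment, gmt)
        b = mn.annotate_communities(sets, assignment, reversed_gmt)
        key = ["community", "pathway"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        assert np.allclose(a.raw_p, b.raw_p)


def test_spinglass_engine_handles_disconnected_graphs():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0)])
    g.add_node("isolated")
    labels, q = spinglass_communities(g, seed=0)
    assert set(labels) == {"a", "b", "c", "isolated"}
    assert labels["isolated"] not in {labels["a"], labels["b"], labels["c"]}
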