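"""Signed module detection, eigengenes, phenotype association and the
permutation d-statistic, checked against closed forms, planted structure
and a brute-force Mann–Whitney enumeration oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import miccnet as mn
from miccnet.coexpression import (
    UNASSIGNED,
    _d_statistic,
    eigengene,
    mann_whitney_two_sided,
    signed_adjacency,
)
from conftest import make_dataset


def brute_force_mw_two_sided(x, y):
    """Exact two-sided Mann–Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(combo)]
        g2 = np.delete(pooled, list(combo))
        u = sum(1 for a in g1 for b in g2 if a > b) \
            + 0.5 * sum(1 for a in g1 for b in g2 if a == b)
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "r,expected",
        [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5**12)],
    )
    def test_closed_form(self, r, expected):
        assert signed_adjacency(np.array([[r]]))[0, 0] == pytest.approx(expected)


class TestDetectModules:
    def test_zero_noise_recovers_planted_partition_exactly(self):
        spec = mn.CompendiumSpec(
            n_datasets=1, genes_master=300, gene_overlap_fraction=1.0,
            samples_per_dataset=100, modules_per_dataset=4, module_size_range=(20, 25),
            n_shared_processes=1, shared_process_sizes=(20,),
            n_neutral_processes=1, neutral_process_size=20, noise_sd=0.0, seed=2,
        )
        datasets, truth = mn.generate_compendium(spec)
        part = mn.detect_modules(datasets[0])
        planted = truth.planted_partition("DS1")
        genes = datasets[0].genes
        ari = adjusted_rand_score(
            [planted[g] for g in genes], [part.assignments[g] for g in genes]
        )
        assert ari == pytest.approx(1.0)

    def test_anticorrelated_blocks_split_in_signed_network(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=30)
        block_up = np.outer(rng.uniform(0.5, 1, 25), e)
        block_down = np.outer(rng.uniform(0.5, 1, 25), -e)
        noise = rng.normal(scale=0.05, size=(50, 30))
        ds = make_dataset(np.vstack([block_up, block_down]) + noise)
        part = mn.detect_modules(ds, min_module_size=20)
        up = {part.assignments[f"g{i}"] for i in range(25)}
        down = {part.assignments[f"g{i}"] for i in range(25, 50)}
        assert len(up) == 1 and len(down) == 1 and up != down
        assert UNASSIGNED not in up | down

    def test_partition_exhaustive_and_min_size(self, compendium, partitions):
        datasets, _ = compendium
        for ds, part in zip(datasets, partitions):
            assert set(part.assignments) == set(ds.genes)
            for genes in part.modules.values():
                assert len(genes) >= 20

    def test_too_few_samples_refused(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(50, 6)))
        with pytest.raises(ValueError, match="sample"):
            mn.detect_modules(ds, min_module_size=10)


class TestEigengene:
    def test_identical_rows_give_normalized_profile(self):
        row = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        ds = make_dataset(np.tile(row, (4, 1)))
        e = eigengene(ds.matrix, ds.genes)
        z = (row - row.mean()) / row.std(ddof=1)
        expected = z / np.linalg.norm(z)
        assert np.allclose(e.to_numpy(), expected, atol=1e-12)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_sign_tracks_mean_profile(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(10, 12))
        ds = make_dataset(m)
        e1 = eigengene(ds.matrix, ds.genes)
        e2 = eigengene(make_dataset(-m).matrix, ds.genes)
        assert np.allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)

    def test_recovers_planted_latent(self, compendium, partitions):
        datasets, truth = compendium
        part = partitions[0]
        ds = datasets[0]
        # match a planted axis module to the detected module holding its genes
        planted_genes = truth.process_genes[sorted(truth.process_genes)[0]]
        label = max(
            part.modules,
            key=lambda m: len(set(part.modules[m]) & planted_genes),
        )
        latent_label = truth.planted_partition(ds.dataset_id)[next(iter(planted_genes))]
        latent = truth.latents[(ds.dataset_id, latent_label)]
        r = np.corrcoef(part.eigengenes[label].to_numpy(), latent.to_numpy())[0, 1]
        assert abs(r) >= 0.95

    def test_degenerate_module_raises(self):
        ds = make_dataset(np.ones((3, 5)))
        with pytest.raises(ValueError, match="zero variance"):
            eigengene(ds.matrix, ds.genes)

    def test_first_pc_explains_most_variance(self, partitions, compendium):
        datasets, _ = compendium
        part, ds = partitions[0], datasets[0]
        label, genes = next(iter(part.modules.items()))
        sub = ds.matrix.loc[genes]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        e = part.eigengenes[label].to_numpy()
        var_e = np.sum((z.to_numpy() @ e) ** 2)
        for row in z.to_numpy():
            u = row / np.linalg.norm(row)
            assert var_e >= np.sum((z.to_numpy() @ u) ** 2) - 1e-9


class TestAssociatePhenotypes:
    def test_flat_eigengene_gives_p_one(self):
        part = mn.ModulePartition(
            "T", {f"g{i}": "M1" for i in range(20)},
            {"M1": pd.Series(np.zeros(12), index=[f"s{i}" for i in range(12)])},
        )
        pheno = pd.DataFrame(
            {"disease_status": ["a"] * 6 + ["b"] * 6},
            index=[f"s{i}" for i in range(12)],
        )
        res = mn.associate_phenotypes(part, pheno)
        assert res[("M1", "disease_status")]["raw_p"] == pytest.approx(1.0)

    def test_exact_mw_small_groups(self):
        stat, p = mann_whitney_two_sided(
            np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])
        )
        assert p == pytest.approx(0.1)

    def test_mw_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (3, 9), (5, 7)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = mann_whitney_two_sided(x, y)
            assert p == pytest.approx(brute_force_mw_two_sided(x, y), abs=1e-12)

    def test_bonferroni_counts_modules_within_phenotype(self, partitions):
        for part in partitions:
            by_pheno = {}
            for (m, ph), res in part.association_results.items():
                by_pheno.setdefault(ph, []).append(res)
            for results in by_pheno.values():
                n = len(results)
                for res in results:
                    assert res["bonferroni_p"] == pytest.approx(
                        min(1.0, res["raw_p"] * n)
                    )

    def test_planted_disease_module_detected_with_power(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            spec = mn.CompendiumSpec(
                n_datasets=1, genes_master=300, gene_overlap_fraction=1.0,
                samples_per_dataset=40, modules_per_dataset=3,
                module_size_range=(20, 25), n_shared_processes=1,
                shared_process_sizes=(25,), n_neutral_processes=1,
                neutral_process_size=25, effect_size=2.0, seed=seed + 100,
            )
            datasets, truth = mn.generate_compendium(spec)
            part = mn.detect_modules(datasets[0])
            res = mn.associate_phenotypes(
                part, datasets[0].phenotypes[["disease_status"]]
            )
            axis = truth.process_genes["AX1"]
            label = max(
                part.modules, key=lambda m: len(set(part.modules[m]) & axis)
            )
            r = res[(label, "disease_status")]
            hits += r["bonferroni_p"] < 0.05 and r["direction"] > 0
        assert hits / n_seeds >= 0.95


class TestSamLikeDE:
    def test_zero_variance_equal_means_gives_zero_d(self):
        x = np.vstack([np.ones(12), np.random.default_rng(0).normal(size=12)])
        g1 = np.arange(12) < 6
        d, _, _ = _d_statistic(x, g1, ~g1)
        assert d[0] == 0.0

    def test_small_groups_rejected(self):
        ds = make_dataset(
            np.random.default_rng(0).normal(size=(10, 5)), groups=["a"] * 2 + ["b"] * 3
        )
        with pytest.raises(ValueError):
            mn.sam_like_de(ds, ("a", "b"))

    def test_exhaustive_enumeration_fallback(self, caplog):
        ds = make_dataset(
            np.random.default_rng(1).normal(size=(30, 8)), groups=["a"] * 4 + ["b"] * 4
        )
        res = mn.sam_like_de(ds, ("a", "b"), n_permutations=1000, seed=0)
        assert res.n_permutations == math.comb(8, 4)

    def test_type_one_error_controlled_under_null(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(rng.normal(size=(500, 20)), groups=["a"] * 10 + ["b"] * 10)
        res = mn.sam_like_de(ds, ("a", "b"), n_permutations=200, seed=1)
        frac = (res.q_value < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 500)
        assert frac <= 0.05 + 2 * se

    def test_planted_shift_recalled(self):
        recalls = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = rng.normal(size=(200, 40))
            m[:20, :20] += 3.0
            ds = make_dataset(m, groups=["d"] * 20 + ["c"] * 20)
            res = mn.sam_like_de(ds, ("d", "c"), n_permutations=200, seed=seed)
            up = set(res.significant_up(0.05))
            recalls.append(len(up & {f"g{i}" for i in range(20)}) / 20)
        assert np.mean(recalls) >= 0.9

    def test_q_monotone_in_abs_d(self):
        ds = make_dataset(
            np.random.default_rng(2).normal(size=(100, 16)), groups=["a"] * 8 + ["b"] * 8
        )
        res = mn.sam_like_de(ds, ("a", "b"), n_permutations=100, seed=2)
        order = np.argsort(-np.abs(res.d_statistic))
        q = res.q_value[order]
        assert (np.diff(q) >= -1e-12).all()
        assert (res.q_value >= 0).all() and (res.q_value <= 1).all()

    def test_gene_rescaling_invariance_with_fixed_s0(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 16))
        g1 = np.arange(16) < 8
        d, s, s0 = _d_statistic(x, g1, ~g1)
        x2 = x.copy()
        x2[7] *= 5.0
        d2, _, _ = _d_statistic(x2, g1, ~g1, s0=s0)
        keep = np.arange(50) != 7
        assert np.allclose(d[keep], d2[keep])
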