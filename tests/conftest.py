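"""Shared fixtures: one reference synthetic compendium and network triple,
with the full MICC pipeline run once per session on each."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import miccnet as mn
from miccnet.micc import attach_phenotype_flags

REFERENCE_SEED = 11


@pytest.fixture(scope="session")
def compendium():
    datasets, truth = mn.generate_compendium(mn.CompendiumSpec(seed=REFERENCE_SEED))
    return datasets, truth


@pytest.fixture(scope="session")
def partitions(compendium):
    datasets, _ = compendium
    parts = []
    for ds in datasets:
        part = mn.detect_modules(ds)
        mn.associate_phenotypes(
            part, ds.phenotypes.drop(columns=["dataset_id", "tissue"])
        )
        parts.append(part)
    return parts


@pytest.fixture(scope="session")
def overlap_network(partitions):
    net = mn.build_overlap_network(partitions)
    attach_phenotype_flags(net)
    return net


@pytest.fixture(scope="session")
def assignment(overlap_network):
    top = mn.detect_top_level(overlap_network)
    return mn.detect_bottom_level(overlap_network, top, seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def node_attributes(overlap_network):
    g = overlap_network.graph
    return {n: dict(g.nodes[n]) for n in g.nodes}


@pytest.fixture(scope="session")
def enrichment(assignment, node_attributes):
    return mn.phenotype_enrichment(assignment, node_attributes)


@pytest.fixture(scope="session")
def network_triple():
    return mn.generate_network_triple(mn.NetworkTripleSpec(seed=REFERENCE_SEED))


def make_dataset(matrix: np.ndarray, genes=None, samples=None, groups=None, dataset_id="T"):
    """Small helper to wrap a raw array as an ExpressionDataset."""
    n_genes, n_samples = matrix.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(matrix, index=genes, columns=samples)
    pheno = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    if groups is not None:
        pheno["disease_status"] = list(groups)
    return mn.ExpressionDataset(df, pheno, "", dataset_id)
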