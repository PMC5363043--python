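"""Synthetic multi-dataset expression compendia and tissue network triples.

The generator plants known structure so every downstream stage has a
ground-truth test surface:

* A *compendium* is a set of expression datasets on partially overlapping
  gene universes.  Each dataset carries disjoint planted co-expression
  modules built as rank-one blocks — a latent per-sample eigengene times
  per-gene loadings drawn uniform in [0.5, 1] — plus Gaussian noise.  A
  subset of modules ("shared processes") reuses the same gene sets across
  datasets and has its eigengene mean shifted upward in disease samples,
  planting a cross-dataset consensus signal.  Background genes are
  independent unit-variance noise.

* A *network triple* is two tissue networks plus a global baseline sharing
  one node set and a backbone of dense communities; each tissue network
  additionally elevates the weights inside its own tissue-specific
  communities, which are therefore recoverable from the differential
  adjacency.

All outputs are fully determined by the spec seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .netquery import FunctionalNetwork
from .preprocess import ExpressionDataset

logger = logging.getLogger(__name__)

TISSUE_CYCLE = ("skin", "lung", "esophagus", "pbmc")


@dataclass
class CompendiumSpec:
    """Parameters of a planted-structure expression compendium.

    Two kinds of cross-dataset structure are planted.  *Shared (disease)
    processes* jointly form a disease axis whose eigengenes shift upward in
    disease samples; each dataset carries the axis as one or more planted
    modules whose granularity cycles across datasets (one dataset sees the
    whole axis as a single module, another splits it per process), the way
    real cohorts partition a common signal differently.  *Neutral
    processes* are shared across datasets but carry no disease effect,
    providing the conserved housekeeping-like background communities of a
    real compendium.  Remaining planted modules are dataset-specific.
    """

    n_datasets: int = 4
    genes_master: int = 1200
    gene_overlap_fraction: float = 0.85
    samples_per_dataset: int = 40
    modules_per_dataset: int = 8
    module_size_range: tuple[int, int] = (20, 35)
    n_shared_processes: int = 3
    shared_process_sizes: tuple[int, ...] = (30, 30, 30)
    n_neutral_processes: int = 3
    neutral_process_size: int = 30
    disease_fraction: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_datasets, self.genes_master, self.samples_per_dataset,
               self.modules_per_dataset) < 1:
            raise ValueError("all counts must be positive")
        if not 0 < self.gene_overlap_fraction <= 1:
            raise ValueError("gene_overlap_fraction must be in (0,1]")
        if not 0 < self.disease_fraction <= 1:
            raise ValueError("disease_fraction must be in (0,1]")
        if self.module_size_range[0] < 3:
            raise ValueError("module_size_range min must be ≥ 3")
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ValueError("module_size_range must be (min, max) with min ≤ max")
        if self.n_shared_processes + self.n_neutral_processes > self.modules_per_dataset:
            raise ValueError(
                "n_shared_processes + n_neutral_processes cannot exceed modules_per_dataset"
            )
        if len(self.shared_process_sizes) != self.n_shared_processes:
            raise ValueError("shared_process_sizes length must equal n_shared_processes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        universe = round(self.gene_overlap_fraction * self.genes_master)
        need = (
            sum(self.shared_process_sizes)
            + self.n_neutral_processes * self.neutral_process_size
            + (self.modules_per_dataset - self.n_shared_processes - self.n_neutral_processes)
            * self.module_size_range[1]
        )
        if need > universe:
            raise ValueError(
                f"infeasible spec: modules need up to {need} genes but each "
                f"dataset universe has only {universe}"
            )


@dataclass
class PartitionTruth:
    """Ground truth of a generated compendium.

    ``module_to_processes`` maps (dataset_id, module label) to the tuple of
    planted process names the module covers (axis modules may cover several
    when a dataset sees the axis at coarse granularity); dataset-specific
    modules map to ``None``.  ``process_genes`` holds the disease-axis
    process gene sets, ``neutral_genes`` the neutral shared processes.
    """

    master_genes: list[str]
    gene_to_module: dict[str, dict[str, str]]  # dataset_id → gene → module
    module_to_processes: dict[tuple[str, str], tuple[str, ...] | None]
    process_genes: dict[str, set[str]]
    neutral_genes: dict[str, set[str]] = field(default_factory=dict)
    latents: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def planted_partition(self, dataset_id: str) -> dict[str, str]:
        return dict(self.gene_to_module[dataset_id])

    @property
    def axis_genes(self) -> set[str]:
        """All genes of the planted disease axis (union of shared processes)."""
        return set().union(*self.process_genes.values()) if self.process_genes else set()

    def is_disease_module(self, dataset_id: str, label: str) -> bool:
        procs = self.module_to_processes.get((dataset_id, label))
        return bool(procs) and any(p in self.process_genes for p in procs)


def _axis_blocks(process_names: list[str], dataset_index: int) -> list[list[str]]:
    """How dataset ``dataset_index`` partitions the axis processes into modules.

    Granularity cycles with the dataset: the first dataset sees the whole
    axis as one module, the next splits it in two, and so on up to the
    per-process split, then the cycle restarts (rotated so block boundaries
    differ between coarse datasets).  Every full cycle contains a
    single-module dataset, which keeps the axis community connected in the
    overlap network.
    """
    k = len(process_names)
    if k == 0:
        return []
    n_blocks = (dataset_index % k) + 1
    rotated = process_names[dataset_index % k:] + process_names[:dataset_index % k]
    blocks: list[list[str]] = [[] for _ in range(n_blocks)]
    for i, name in enumerate(rotated):
        blocks[i % n_blocks].append(name)
    return [sorted(b) for b in blocks]


def generate_compendium(
    spec: CompendiumSpec,
) -> tuple[list[ExpressionDataset], PartitionTruth]:
    """Generate the datasets of a planted compendium plus their ground truth."""
    spec.validate()
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    width = len(str(spec.genes_master))
    master = [f"G{i:0{width}d}" for i in range(spec.genes_master)]
    universe_size = round(spec.gene_overlap_fraction * spec.genes_master)

    # shared-process gene sets, disjoint, forced into every dataset universe
    pool = list(master)
    root.shuffle(pool)
    process_genes: dict[str, set[str]] = {}
    neutral_genes: dict[str, set[str]] = {}
    cursor = 0
    for p, size in enumerate(spec.shared_process_sizes, start=1):
        process_genes[f"AX{p}"] = set(pool[cursor:cursor + size])
        cursor += size
    for p in range(1, spec.n_neutral_processes + 1):
        neutral_genes[f"NP{p}"] = set(pool[cursor:cursor + spec.neutral_process_size])
        cursor += spec.neutral_process_size
    all_shared = set().union(*process_genes.values(), *neutral_genes.values()) \
        if (process_genes or neutral_genes) else set()
    forced = sorted(all_shared)
    remaining_master = [g for g in master if g not in all_shared]
    axis_names = sorted(process_genes)

    datasets: list[ExpressionDataset] = []
    gene_to_module: dict[str, dict[str, str]] = {}
    module_to_processes: dict[tuple[str, str], tuple[str, ...] | None] = {}
    latents: dict[tuple[str, str], pd.Series] = {}
    for d in range(spec.n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(spec.n_datasets)[d])
        dataset_id = f"DS{d + 1}"
        tissue = TISSUE_CYCLE[d % len(TISSUE_CYCLE)]
        n_extra = universe_size - len(forced)
        if n_extra < 0:
            raise ValueError(
                f"infeasible spec for dataset {dataset_id}: shared processes "
                f"({len(forced)} genes) exceed the universe ({universe_size})"
            )
        extra = list(rng.choice(remaining_master, size=n_extra, replace=False))
        universe = sorted(all_shared | set(extra))

        assignments = {g: "background" for g in universe}
        modules: dict[str, list[str]] = {}
        blocks = _axis_blocks(axis_names, d)
        for j, block in enumerate(blocks, start=1):
            label = f"A{j}"
            genes = sorted(set().union(*(process_genes[p] for p in block)))
            modules[label] = genes
            module_to_processes[(dataset_id, label)] = tuple(block)
        for p_name, genes in neutral_genes.items():
            modules[p_name] = sorted(genes)
            module_to_processes[(dataset_id, p_name)] = (p_name,)
        free = [g for g in universe if g not in all_shared]
        rng.shuffle(free)
        cursor = 0
        n_specific = spec.modules_per_dataset - spec.n_neutral_processes - len(blocks)
        for j in range(max(0, n_specific)):
            size = int(rng.integers(spec.module_size_range[0], spec.module_size_range[1] + 1))
            label = f"S{j + 1}"
            modules[label] = sorted(free[cursor:cursor + size])
            module_to_processes[(dataset_id, label)] = None
            cursor += size
        for label, genes in modules.items():
            for g in genes:
                assignments[g] = label
        gene_to_module[dataset_id] = assignments

        n = spec.samples_per_dataset
        samples = [f"{dataset_id}_S{i + 1:03d}" for i in range(n)]
        n_disease = round(spec.disease_fraction * n)
        status = np.array(["control"] * n, dtype=object)
        status[rng.choice(n, size=n_disease, replace=False)] = "disease"
        disease = (status == "disease").astype(float)

        matrix = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(len(universe), n)), index=universe, columns=samples
        )
        for label, genes in modules.items():
            e = rng.normal(0.0, 1.0, size=n)
            procs = module_to_processes[(dataset_id, label)]
            if procs is not None and any(p in process_genes for p in procs):
                e = e + spec.effect_size * disease
            loadings = rng.uniform(0.5, 1.0, size=len(genes))
            noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), n)) if spec.noise_sd > 0 else 0.0
            matrix.loc[genes] = np.outer(loadings, e) + noise
            latents[(dataset_id, label)] = pd.Series(e, index=samples)

        phenotypes = pd.DataFrame(
            {
                "dataset_id": dataset_id,
                "tissue": tissue,
                "disease_status": status,
                "severity": rng.uniform(0.0, 10.0, size=n),
            },
            index=pd.Index(samples, name="sample_id"),
        )
        datasets.append(ExpressionDataset(matrix, phenotypes, tissue, dataset_id))
    truth = PartitionTruth(
        master, gene_to_module, module_to_processes, process_genes, neutral_genes, latents
    )
    _check_compendium_invariants(datasets, truth)
    return datasets, truth


def _check_compendium_invariants(
    datasets: list[ExpressionDataset], truth: PartitionTruth
) -> None:
    for p_name, genes in truth.process_genes.items():
        n_universes = sum(1 for ds in datasets if genes <= set(ds.genes))
        if len(datasets) >= 2 and n_universes < 2:
            raise AssertionError(f"shared process {p_name} present in <2 universes")


@dataclass
class NetworkTripleSpec:
    """Parameters of a (tissue A, tissue B, global) functional-network triple.

    Besides the dense backbone and tissue-specific communities, a fraction
    of the remaining gene pairs carry *connector* edges with probabilities
    above typical pruning thresholds, identical across the three networks.
    They keep the pruned query subgraphs connected (so the largest component
    spans the backbone, as in real probability networks) while cancelling
    exactly in the differential adjacency.
    """

    n_genes: int = 150
    backbone_communities: int = 3
    tissue_specific_communities_per_tissue: int = 2
    community_size: int = 15
    within_weight_mean: float = 0.9
    between_weight_mean: float = 0.1
    connector_fraction: float = 0.08
    connector_weight_range: tuple[float, float] = (0.55, 0.75)
    weight_noise_sd: float = 0.05
    seed: int = 0
    tissue_a: str = "lung"
    tissue_b: str = "skin"

    def validate(self) -> None:
        for name in ("within_weight_mean", "between_weight_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        lo, hi = self.connector_weight_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"connector_weight_range {self.connector_weight_range} outside [0,1]")
        if not 0.0 <= self.connector_fraction <= 1.0:
            raise ValueError("connector_fraction must be in [0,1]")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be nonnegative")
        need = (
            self.backbone_communities * self.community_size
            + 2 * self.tissue_specific_communities_per_tissue * self.community_size
        )
        if need > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {need} community member genes"
            )


@dataclass
class NetworkTruth:
    """Planted structure of a generated network triple."""

    backbone: dict[str, int]
    tissue_specific: dict[str, list[set[str]]]
    nodes: list[str]

    def tissue_partition(self, tissue: str) -> dict[str, int]:
        """Gene → planted community index over that tissue's specific genes."""
        out: dict[str, int] = {}
        for i, genes in enumerate(self.tissue_specific[tissue]):
            for g in genes:
                out[g] = i
        return out


def generate_network_triple(
    spec: NetworkTripleSpec,
) -> tuple[FunctionalNetwork, FunctionalNetwork, FunctionalNetwork, NetworkTruth]:
    """Generate (tissue A, tissue B, global) networks with planted structure."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7)))
    width = len(str(spec.n_genes))
    nodes = [f"N{i:0{width}d}" for i in range(spec.n_genes)]
    n = spec.n_genes

    backbone: dict[str, int] = {}
    cursor = 0
    for c in range(spec.backbone_communities):
        for g in nodes[cursor:cursor + spec.community_size]:
            backbone[g] = c
        cursor += spec.community_size
    tissue_specific: dict[str, list[set[str]]] = {spec.tissue_a: [], spec.tissue_b: []}
    for tissue in (spec.tissue_a, spec.tissue_b):
        for _ in range(spec.tissue_specific_communities_per_tissue):
            tissue_specific[tissue].append(set(nodes[cursor:cursor + spec.community_size]))
            cursor += spec.community_size

    base = np.full((n, n), spec.between_weight_mean)
    comm = np.array([backbone.get(g, -1) for g in nodes])
    same = (comm[:, None] == comm[None, :]) & (comm[:, None] >= 0)
    base[same] = spec.within_weight_mean

    # connector edges: identical in all three networks, only on pairs outside
    # every planted community, so they cancel in the differential adjacency
    index = {g: i for i, g in enumerate(nodes)}
    planted_same = same.copy()
    for sets in tissue_specific.values():
        for genes in sets:
            sel = [index[g] for g in genes]
            planted_same[np.ix_(sel, sel)] = True
    eligible = np.triu(~planted_same, k=1)
    conn_mask = eligible & (
        np.triu(rng.random((n, n)), k=1) < spec.connector_fraction
    )
    lo, hi = spec.connector_weight_range
    conn_weights = rng.uniform(lo, hi, size=(n, n))
    base = np.where(conn_mask | conn_mask.T, np.maximum(conn_weights, conn_weights.T), base)

    def tissue_matrix(tissue: str | None) -> np.ndarray:
        a = base.copy()
        if tissue is not None:
            for genes in tissue_specific[tissue]:
                sel = [index[g] for g in genes]
                a[np.ix_(sel, sel)] = spec.within_weight_mean
        if spec.weight_noise_sd > 0:
            noise = rng.normal(0.0, spec.weight_noise_sd, size=(n, n))
            noise = np.triu(noise, k=1)
            a = a + noise + noise.T
        clipped = np.clip(a, 0.0, 1.0)
        frac = float((clipped != a)[np.triu_indices(n, k=1)].mean())
        if frac > 0:
            logger.info("network %r: clipped %.3f of edge weights into [0,1]", tissue, frac)
        np.fill_diagonal(clipped, 0.0)
        return clipped

    def to_network(a: np.ndarray, tissue: str) -> FunctionalNetwork:
        edges = [
            (nodes[i], nodes[j], float(a[i, j]))
            for i, j in combinations(range(n), 2)
            if a[i, j] > 0
        ]
        return FunctionalNetwork.from_edges(edges, tissue)

    net_a = to_network(tissue_matrix(spec.tissue_a), spec.tissue_a)
    net_b = to_network(tissue_matrix(spec.tissue_b), spec.tissue_b)
    net_global = to_network(tissue_matrix(None), "global")
    return net_a, net_b, net_global, NetworkTruth(backbone, tissue_specific, nodes)


def generate_genesets(
    truth: PartitionTruth,
    decoys: int = 0,
    include_neutral: bool = True,
    seed: int = 0,
) -> dict[str, dict]:
    """GMT-style collection: planted shared-process sets plus random decoys.

    Emits the disease-axis process gene sets (and, by default, the neutral
    shared processes) as "pathways", plus ``decoys`` random sets whose sizes
    cycle through the planted sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    collection: dict[str, dict] = {}
    planted = dict(sorted(truth.process_genes.items()))
    if include_neutral:
        planted.update(sorted(truth.neutral_genes.items()))
    for name, genes in planted.items():
        collection[name] = {
            "description": "planted shared process",
            "genes": sorted(genes),
        }
    sizes = [len(g) for g in planted.values()] or [30]
    for d in range(decoys):
        size = sizes[d % len(sizes)]
        genes = sorted(rng.choice(truth.master_genes, size=size, replace=False))
        collection[f"DECOY{d + 1}"] = {"description": "random decoy set", "genes": genes}
    return collection


# ---------------------------------------------------------------------------
# file emission / round-trip

def write_compendium(
    datasets: list[ExpressionDataset], truth: PartitionTruth, out_dir: str | Path
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for ds in datasets:
        expr = out / f"{ds.dataset_id}_expression.tsv"
        pheno = out / f"{ds.dataset_id}_phenotypes.tsv"
        io.write_expression(ds.matrix, expr)
        io.write_phenotypes(ds.phenotypes, pheno)
        tmap = out / f"{ds.dataset_id}_truth_modules.tsv"
        io.write_two_column_map(truth.gene_to_module[ds.dataset_id], tmap)
        written += [expr, pheno, tmap]
    return written


def read_compendium(out_dir: str | Path) -> list[ExpressionDataset]:
    out = Path(out_dir)
    datasets = []
    for expr in sorted(out.glob("*_expression.tsv")):
        dataset_id = expr.name.removesuffix("_expression.tsv")
        matrix = io.read_expression(expr)
        phenotypes = io.read_phenotypes(out / f"{dataset_id}_phenotypes.tsv")
        tissue = str(phenotypes["tissue"].iloc[0]) if "tissue" in phenotypes else ""
        datasets.append(ExpressionDataset(matrix, phenotypes, tissue, dataset_id))
    return datasets


def write_network_triple(
    networks: tuple[FunctionalNetwork, FunctionalNetwork, FunctionalNetwork],
    truth: NetworkTruth,
    out_dir: str | Path,
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for net in networks:
        path = out / f"network_{net.tissue}.tsv"
        net.to_tsv(path)
        written.append(path)
    io.write_two_column_map(
        {g: str(c) for g, c in truth.backbone.items()},
        out / "truth_backbone.tsv",
        header=("gene_id", "community"),
    )
    for tissue, sets in truth.tissue_specific.items():
        mapping = {g: str(i) for i, genes in enumerate(sets) for g in sorted(genes)}
        io.write_two_column_map(
            mapping, out / f"truth_specific_{tissue}.tsv", header=("gene_id", "community")
        )
    return written
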