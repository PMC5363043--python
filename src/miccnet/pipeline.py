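"""End-to-end orchestration of the multi-network analysis from one config.

Stages run in a fixed order — preprocess, module detection, phenotype
association, module overlap network, hierarchical communities, community
enrichment and pathway annotation, consensus gene derivation — with
optional functional-network query, differential network and gene-set
scoring stages when the config supplies the corresponding inputs.  A single
global seed fans out deterministically to per-stage child seeds, every
artifact is written as TSV, and a JSON manifest records stages, parameters,
outputs and checksums so a rerun with the same config is checksum-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import communities as communities_mod
from . import diffnet as diffnet_mod
from . import io, micc, netquery, scoring
from .coexpression import associate_phenotypes, detect_modules
from .preprocess import ExpressionDataset, collapse_duplicates, filter_missingness, zscore

logger = logging.getLogger(__name__)

DEFAULT_PARAMETERS: dict = {
    "power": 12,
    "min_module_size": 20,
    "merge_height": 0.15,
    "max_missing": 0.20,
    "threshold_policy": "positive+hypergeometric",
    "alpha": 0.05,
    "n_permutations": 1000,
    "max_communities": 10,
    "prune_below": 0.5,
    "group_column": "disease_status",
}

_RANGES = {
    "power": (1, 30),
    "min_module_size": (3, 10_000),
    "merge_height": (0.0, 1.0),
    "max_missing": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "n_permutations": (1, 10_000_000),
    "max_communities": (2, 100),
    "prune_below": (0.0, 1.0),
}

_TOP_KEYS = {
    "seed", "output_dir", "datasets", "parameters", "pathways_gmt",
    "functional_networks", "score_gmt", "selected_communities",
}


def validate_config(path: str | Path) -> dict:
    """Parse, default-fill and range-check a pipeline config.

    Raises ``ValueError`` with an itemized report when the config is invalid;
    returns the normalized config dict otherwise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown key {key!r}")
    if "seed" not in raw:
        problems.append("missing required key 'seed'")
    if not raw.get("datasets"):
        problems.append("missing or empty 'datasets' manifest")
    params = dict(DEFAULT_PARAMETERS)
    params.update(raw.get("parameters") or {})
    for key in (raw.get("parameters") or {}):
        if key not in DEFAULT_PARAMETERS:
            problems.append(f"unknown parameter {key!r}")
    for key, (lo, hi) in _RANGES.items():
        v = params.get(key)
        if v is not None and not (lo <= v <= hi):
            problems.append(f"parameter {key}={v} outside [{lo}, {hi}]")
    seen_ids: set[str] = set()
    base = Path(path).parent
    for entry in raw.get("datasets") or []:
        dsid = entry.get("dataset_id")
        if dsid in seen_ids:
            problems.append(f"duplicate dataset_id {dsid!r}")
        seen_ids.add(dsid)
        for k in ("expression", "phenotypes"):
            if k not in entry:
                problems.append(f"dataset {dsid!r}: missing {k!r} path")
            elif not (base / entry[k]).exists() and not Path(entry[k]).exists():
                problems.append(f"dataset {dsid!r}: path {entry[k]!r} does not exist")
    if problems:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(problems))
    config = dict(raw)
    config["parameters"] = params
    config.setdefault("output_dir", "miccnet_out")
    config["_base_dir"] = str(base)
    return config


def _resolve(base: str, p: str) -> Path:
    cand = Path(base) / p
    return cand if cand.exists() else Path(p)


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 1_000_003 + stage * 7919 + 1) % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured analysis end to end; returns the run manifest."""
    if not isinstance(config, dict):
        config = validate_config(config)
    seed = int(config["seed"])
    params = config["parameters"]
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    base = config.get("_base_dir", ".")
    manifest: dict = {"stages": [], "seed": seed, "parameters": params}
    outputs: list[Path] = []

    def record(stage: str, t0: float, files: list[Path], **extra) -> None:
        outputs.extend(files)
        manifest["stages"].append(
            {
                "stage": stage,
                "seconds": round(time.time() - t0, 3),
                "outputs": [str(f) for f in files],
                **extra,
            }
        )
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    try:
        # --- preprocess -----------------------------------------------------
        t0 = time.time()
        datasets: list[ExpressionDataset] = []
        for entry in config["datasets"]:
            ds = ExpressionDataset(
                io.read_expression(_resolve(base, entry["expression"])),
                io.read_phenotypes(_resolve(base, entry["phenotypes"])),
                entry.get("tissue", ""),
                entry["dataset_id"],
            )
            ds = collapse_duplicates(ds)
            ds = filter_missingness(ds, params["max_missing"])
            datasets.append(ds)
        record("preprocess", t0, [], datasets=[d.dataset_id for d in datasets])

        # --- modules + association ------------------------------------------
        t0 = time.time()
        partitions = []
        files = []
        for ds in datasets:
            part = detect_modules(
                ds,
                power=params["power"],
                min_module_size=params["min_module_size"],
                merge_height=params["merge_height"],
            )
            associate_phenotypes(
                part, ds.phenotypes.drop(columns=["dataset_id", "tissue"], errors="ignore")
            )
            partitions.append(part)
            f = out / f"{ds.dataset_id}_modules.tsv"
            io.write_two_column_map(part.assignments, f)
            files.append(f)
            fa = out / f"{ds.dataset_id}_associations.tsv"
            part.association_frame().to_csv(fa, sep="\t", index=False)
            files.append(fa)
        record("modules", t0, files)

        # --- overlap network ------------------------------------------------
        t0 = time.time()
        network = micc.build_overlap_network(
            partitions, threshold_policy=params["threshold_policy"], alpha=params["alpha"]
        )
        micc.attach_phenotype_flags(network, alpha=params["alpha"])
        f = out / "overlap_network_edges.tsv"
        io.write_edge_list(
            sorted(
                ("|".join(u), "|".join(v), d["weight"])
                for u, v, d in network.graph.edges(data=True)
            ),
            f,
        )
        record("overlap_network", t0, [f], n_edges=network.graph.number_of_edges())

        # --- communities ----------------------------------------------------
        t0 = time.time()
        top = communities_mod.detect_top_level(network)
        assignment = communities_mod.detect_bottom_level(
            network, top, max_communities=params["max_communities"],
            seed=_stage_seed(seed, 4),
        )
        mod_test = communities_mod.modularity_permutation_test(
            network, assignment, n_permutations=params["n_permutations"],
            seed=_stage_seed(seed, 5),
        )
        f = out / "communities.tsv"
        assignment.frame().to_csv(f, sep="\t", index=False)
        record(
            "communities", t0, [f],
            modularity=mod_test["observed_Q"], modularity_p=mod_test["p_raw"],
        )

        # --- enrichment + annotation ----------------------------------------
        t0 = time.time()
        attrs = {n: dict(network.graph.nodes[n]) for n in network.graph.nodes}
        enrichment = communities_mod.phenotype_enrichment(assignment, attrs)
        f = out / "community_phenotype_enrichment.tsv"
        enrichment.to_csv(f, sep="\t", index=False)
        files = [f]
        edge_sets = communities_mod.edge_gene_sets(network)
        if config.get("pathways_gmt"):
            pathways = io.read_gmt(_resolve(base, config["pathways_gmt"]))
            annot = communities_mod.annotate_communities(edge_sets, assignment, pathways)
            fa = out / "community_pathway_annotation.tsv"
            annot.to_csv(fa, sep="\t", index=False)
            files.append(fa)
        record("enrichment", t0, files)

        # --- consensus ------------------------------------------------------
        t0 = time.time()
        selected = config.get("selected_communities") or consensus_mod.select_disease_communities(
            enrichment, assignment, attrs, alpha=params["alpha"]
        )
        cons = consensus_mod.derive_tissue_consensus(partitions, assignment, selected)
        f = out / "consensus_genes.tsv"
        cons.frame().to_csv(f, sep="\t", index=False)
        fs = out / "consensus_sizes.tsv"
        pd.DataFrame(
            [{"tissue": t, "n_genes": len(g)} for t, g in sorted(cons.per_tissue.items())]
            + [{"tissue": "union", "n_genes": len(cons.union_set)}]
        ).to_csv(fs, sep="\t", index=False)
        record("consensus", t0, [f, fs], selected_communities=selected)

        # --- optional functional-network stages -----------------------------
        nets = config.get("functional_networks") or {}
        if nets and cons.union_set:
            t0 = time.time()
            files = []
            loaded = {
                name: netquery.FunctionalNetwork.from_tsv(_resolve(base, p), tissue=name)
                for name, p in nets.items()
            }
            results = {}
            for name, net in loaded.items():
                res = netquery.query_network(
                    net, sorted(cons.union_set), prune_below=params["prune_below"],
                    seed=_stage_seed(seed, 8),
                )
                netquery.find_hubs(res)
                if len(set(res.functional_modules.values())) >= 2:
                    netquery.find_bridges(res)
                results[name] = res
                f = out / f"query_{name}_nodes.tsv"
                rows = [
                    {
                        "gene": g,
                        "module": m,
                        "is_hub": any(g in h for h in res.hubs.values()),
                        "is_bridge": g in set(res.bridges),
                    }
                    for g, m in sorted(res.functional_modules.items())
                ]
                pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
                files.append(f)
            record("netquery", t0, files)

            if {"focal", "comparator", "baseline"} <= set(loaded):
                t0 = time.time()
                common = diffnet_mod.common_nodes(results["focal"], results["comparator"])
                diff = diffnet_mod.differential_adjacency(
                    loaded["focal"], loaded["comparator"], loaded["baseline"], common
                )
                modules = diffnet_mod.differential_communities(
                    diff, seed=_stage_seed(seed, 9)
                )
                f = out / "differential_edges.tsv"
                io.write_edge_list(diff.edges(), f)
                fm = out / "differential_modules.tsv"
                io.write_two_column_map(
                    {g: str(m) for g, m in sorted(modules.items())}, fm,
                    header=("gene_id", "module"),
                )
                record("diffnet", t0, [f, fm], n_nodes=len(common))

        if config.get("score_gmt"):
            t0 = time.time()
            sets = io.read_gmt(_resolve(base, config["score_gmt"]))
            files = []
            for ds in datasets:
                z = zscore(ds)
                table = scoring.score_genesets(z, sets)
                comp = scoring.compare_groups(
                    table, ds.phenotypes[params["group_column"]]
                )
                f = out / f"{ds.dataset_id}_geneset_scores.tsv"
                table.scores.to_csv(f, sep="\t")
                fc = out / f"{ds.dataset_id}_geneset_comparison.tsv"
                comp.to_csv(fc, sep="\t", index=False)
                files += [f, fc]
            record("scoring", t0, files)
    except Exception as exc:
        manifest["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["checksums"] = {str(f): _checksum(f) for f in outputs if f.exists()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
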