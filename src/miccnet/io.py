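"""Readers and writers for the plain-text formats used throughout the package.

Expression matrices are genes x samples TSV with a header row of sample IDs
and gene IDs in the first column.  Phenotype tables are sample-per-row TSV.
Networks are 3-column edge lists (gene_a, gene_b, weight).  Gene sets use the
standard GMT layout (name, description, tab-separated members).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a weighted edge list TSV (gene_a, gene_b, weight), header optional."""
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (i == 0 and _is_header(row)):
                continue
            edges.append((row[0], row[1], float(row[2])))
    return edges


def _is_header(row: list[str]) -> bool:
    try:
        float(row[2])
        return False
    except (ValueError, IndexError):
        return True


def write_edge_list(
    edges: list[tuple[str, str, float]], path: str | Path, header: bool = True
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        if header:
            w.writerow(["gene_a", "gene_b", "weight"])
        for a, b, wt in edges:
            w.writerow([a, b, repr(float(wt))])


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT gene-set file into {name: {genes, description}}."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 3:
                continue
            sets[row[0]] = {"description": row[1], "genes": list(row[2:])}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for name, rec in sets.items():
            w.writerow([name, rec.get("description", "")] + list(rec["genes"]))


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Read a key→value TSV map (e.g. gene→module assignments)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row:
                continue
            if i == 0 and row[0].lower() in {"gene", "gene_id", "node", "key"}:
                continue
            out[row[0]] = row[1]
    return out


def write_two_column_map(
    mapping: dict[str, str], path: str | Path, header: tuple[str, str] = ("gene_id", "module")
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(list(header))
        for k in mapping:
            w.writerow([k, mapping[k]])
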