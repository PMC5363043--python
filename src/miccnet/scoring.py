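"""Single-sample gene-set scores and group comparisons.

A gene set's score in a sample is the average of the member genes'
z-scores in that sample — a one-number-per-sample summary of set
expression, comparable across sets and samples because every gene is
standardized.  Sets with too few measured genes on a platform are flagged
rather than scored.  Group differences per set are tested with a two-sided
Mann–Whitney U; raw p-values are reported by default, with an optional
Benjamini–Hochberg column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coexpression import mann_whitney_two_sided

logger = logging.getLogger(__name__)


@dataclass
class SampleScoreTable:
    """(sample x gene set) average z-scores plus per-set coverage."""

    scores: pd.DataFrame
    coverage: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def score_genesets(
    z_matrix: pd.DataFrame,
    collection: dict[str, dict],
    min_coverage: float = 0.5,
) -> SampleScoreTable:
    """Average z-score per (sample, gene set) over the set's measured genes.

    ``coverage`` is the fraction of set genes present in the z-matrix; sets
    below ``min_coverage`` (or with no measured genes) are flagged and not
    scored.
    """
    measured = set(z_matrix.index)
    cols: dict[str, pd.Series] = {}
    coverage: dict[str, float] = {}
    skipped: list[str] = []
    for name in sorted(collection):
        genes = list(dict.fromkeys(collection[name]["genes"]))
        present = [g for g in genes if g in measured]
        cov = len(present) / len(genes) if genes else 0.0
        coverage[name] = cov
        if not present or cov < min_coverage:
            logger.warning(
                "gene set %r: coverage %.2f below %.2f; not scored", name, cov, min_coverage
            )
            skipped.append(name)
            continue
        cols[name] = z_matrix.loc[present].mean(axis=0, skipna=True)
    scores = pd.DataFrame(cols, index=z_matrix.columns)
    return SampleScoreTable(scores, coverage, skipped)


def compare_groups(
    scores: SampleScoreTable | pd.DataFrame,
    grouping: pd.Series,
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per gene set between two sample groups.

    ``grouping`` maps sample IDs to exactly two levels with ≥3 samples each.
    Direction is the sign of the median score difference (second sorted
    level minus first).  ``adjust=True`` adds a Benjamini–Hochberg column.
    """
    table = scores.scores if isinstance(scores, SampleScoreTable) else scores
    grouping = grouping.reindex(table.index).dropna().astype(str)
    levels = sorted(grouping.unique())
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {levels}")
    idx_a = grouping.index[grouping == levels[0]]
    idx_b = grouping.index[grouping == levels[1]]
    if min(len(idx_a), len(idx_b)) < 3:
        raise ValueError("both groups need ≥3 samples")
    rows = []
    for name in table.columns:
        a = table.loc[idx_a, name].dropna().to_numpy(dtype=float)
        b = table.loc[idx_b, name].dropna().to_numpy(dtype=float)
        stat, p = mann_whitney_two_sided(b, a)
        rows.append(
            {
                "gene_set": name,
                "group_low": levels[0],
                "group_high": levels[1],
                "U": stat,
                "p_value": p,
                "direction": float(np.sign(np.median(b) - np.median(a))),
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["bh_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
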