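"""Gene-level collapsing, missingness filtering and per-gene z-scoring.

These operations take a genes x samples expression matrix (log-scale values
or log ratios) and prepare it for co-expression clustering and gene-set
scoring.  Duplicate probe rows mapping to the same gene ID are collapsed to
the gene mean and median-centred; genes with too much missing data are
removed; z-scoring standardizes each gene to mean 0, unit standard deviation
so that set scores are comparable across genes.

Missing values are handled pairwise-complete throughout: means, medians and
standard deviations ignore NaN, and NaN entries propagate through z-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """One cohort: a genes x samples matrix with its per-sample phenotype table.

    ``matrix`` rows are indexed by stable gene IDs, columns by sample IDs.
    ``phenotypes`` is indexed by sample ID and may mix two-class categorical
    and continuous columns.
    """

    matrix: pd.DataFrame
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    tissue: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if len(self.phenotypes) and not self.phenotypes.index.equals(self.matrix.columns):
            missing = set(self.matrix.columns) ^ set(self.phenotypes.index)
            if missing:
                raise ValueError(
                    f"dataset {self.dataset_id!r}: sample IDs of matrix and "
                    f"phenotype table differ: {sorted(missing)[:5]}"
                )
            self.phenotypes = self.phenotypes.loc[self.matrix.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)


def collapse_duplicates(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse rows sharing a gene ID to the mean, then median-centre each gene.

    The mean ignores missing values.  After collapsing, every gene row is
    shifted so its (NaN-ignoring) median is zero.
    """
    if dataset.matrix.empty:
        raise ValueError("cannot collapse an empty expression matrix")
    collapsed = dataset.matrix.groupby(level=0, sort=False).mean()
    centred = collapsed.sub(collapsed.median(axis=1, skipna=True), axis=0)
    return ExpressionDataset(centred, dataset.phenotypes, dataset.tissue, dataset.dataset_id)


def filter_missingness(
    dataset: ExpressionDataset, max_missing: float = 0.20
) -> ExpressionDataset:
    """Retain genes whose missing fraction is <= ``max_missing`` (order preserved)."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must be in [0,1], got {max_missing}")
    frac = dataset.matrix.isna().mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        logger.warning(
            "dataset %r: missingness filter removed all %d genes",
            dataset.dataset_id, len(keep),
        )
    return ExpressionDataset(
        dataset.matrix.loc[keep], dataset.phenotypes, dataset.tissue, dataset.dataset_id
    )


def zscore(dataset: ExpressionDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores: (x - gene mean) / gene sd, with the n-1 sd denominator.

    Zero-variance genes are dropped with a warning rather than producing
    infinities; NaN entries propagate.
    """
    matrix = dataset.matrix if isinstance(dataset, ExpressionDataset) else dataset
    mu = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, ddof=1, skipna=True)
    degenerate = ~(sd > 0) | ~np.isfinite(sd)
    if degenerate.any():
        logger.warning(
            "zscore: dropping %d zero-variance gene(s): %s",
            int(degenerate.sum()), list(matrix.index[degenerate])[:5],
        )
    keep = ~degenerate
    return matrix.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
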