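"""Signed weighted co-expression module detection and module-level statistics.

A signed co-expression network maps the Pearson correlation ``r`` of every
gene pair to an adjacency ``((1 + r) / 2) ** power`` so that strongly
anti-correlated genes get adjacency near zero and end up in different
modules.  Modules are cut from an average-linkage tree built on the
topological overlap dissimilarity of that adjacency, then merged when their
eigengenes are nearly collinear.  Each module is summarized by its
eigengene — the first principal component of the standardized module
submatrix — which is tested against sample phenotypes (Mann–Whitney U for
two-class variables, Spearman for continuous ones, Bonferroni per phenotype).

A permutation d-statistic in the style of Significance Analysis of
Microarrays provides per-gene differential expression with q-values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, spearmanr

from .preprocess import ExpressionDataset

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ModulePartition:
    """Assignment of one dataset's genes to labeled co-expression modules.

    ``assignments`` maps every gene of the dataset to a module label (or
    ``"unassigned"``).  ``eigengenes`` maps module label to a unit-norm
    per-sample vector.  ``universe`` is the full measured gene list, which
    downstream overlap statistics use as the sampling frame.
    """

    dataset_id: str
    assignments: dict[str, str]
    eigengenes: dict[str, pd.Series] = field(default_factory=dict)
    association_results: dict[tuple[str, str], dict] = field(default_factory=dict)
    tissue: str = ""

    @property
    def universe(self) -> list[str]:
        return list(self.assignments)

    @property
    def modules(self) -> dict[str, list[str]]:
        """Module label → member genes, excluding the unassigned label."""
        out: dict[str, list[str]] = {}
        for g, m in self.assignments.items():
            if m != UNASSIGNED:
                out.setdefault(m, []).append(g)
        return out

    def association_frame(self) -> pd.DataFrame:
        rows = [
            {"module": m, "phenotype": p, **res}
            for (m, p), res in self.association_results.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class DEResult:
    """Per-gene SAM-style permutation differential expression result."""

    genes: list[str]
    d_statistic: np.ndarray
    q_value: np.ndarray
    contrast: tuple[str, str]
    n_permutations: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d_statistic": self.d_statistic, "q_value": self.q_value}, index=self.genes
        )

    def significant_up(self, fdr: float = 0.05) -> list[str]:
        mask = (self.q_value < fdr) & (self.d_statistic > 0)
        return [g for g, keep in zip(self.genes, mask) if keep]


def _pairwise_correlation(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        # pairwise-complete path (imputation is out of scope)
        return matrix.T.corr().to_numpy()
    return np.corrcoef(x)


def signed_adjacency(correlation: np.ndarray, power: float = 12) -> np.ndarray:
    """Signed soft-thresholded adjacency ((1 + r)/2)^power."""
    return ((1.0 + correlation) / 2.0) ** power


def topological_overlap_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    """1 - TOM, where TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def eigengene(matrix: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Returned as a unit-norm per-sample vector, sign-oriented so that its
    correlation with the module's mean standardized profile is non-negative.
    """
    sub = matrix.loc[module_genes]
    if len(sub) < 2:
        raise ValueError(f"module of {len(sub)} gene(s) has no eigengene")
    mu = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    if not (sd > 0).all():
        bad = list(sub.index[~(sd > 0)])
        raise ValueError(f"degenerate module genes with zero variance: {bad[:5]}")
    z = sub.sub(mu, axis=0).div(sd, axis=0).to_numpy(dtype=float)
    z = np.where(np.isfinite(z), z, 0.0)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    mean_profile = z.mean(axis=0)
    if float(v @ mean_profile) < 0:
        v = -v
    return pd.Series(v, index=matrix.columns)


def detect_modules(
    dataset: ExpressionDataset,
    power: float = 12,
    min_module_size: int = 20,
    merge_height: float = 0.15,
    cut_height: float = 0.8,
) -> ModulePartition:
    """Detect signed co-expression modules in one dataset.

    Pipeline: signed adjacency → topological overlap dissimilarity →
    average-linkage hierarchical clustering → static cut of the tree at
    dissimilarity ``cut_height`` → drop clusters below ``min_module_size``
    → merge modules whose eigengenes correlate above ``1 - merge_height``.
    Genes in no surviving module are labeled ``"unassigned"``.  Module
    labels are ``M1, M2, ...`` by decreasing size.

    The static cut height is on the TOM-dissimilarity scale: unrelated gene
    pairs sit near 1, co-module pairs well below; 0.8 separates the two
    regimes with a wide margin and is exposed for tuning.
    """
    n_samples = dataset.matrix.shape[1]
    if n_samples < 8:
        raise ValueError(
            f"dataset {dataset.dataset_id!r} has {n_samples} samples; "
            "correlations are unstable below 8"
        )
    if dataset.matrix.shape[0] < 2 * min_module_size:
        raise ValueError(
            f"dataset {dataset.dataset_id!r} has too few genes "
            f"({dataset.matrix.shape[0]}) for min_module_size={min_module_size}"
        )
    genes = list(dataset.matrix.index)
    corr = _pairwise_correlation(dataset.matrix)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    diss = topological_overlap_dissimilarity(signed_adjacency(corr, power))
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    tree = linkage(squareform(diss, checks=False), method="average")
    raw_labels = fcluster(tree, t=float(cut_height), criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, raw_labels):
        clusters.setdefault(int(lab), []).append(g)
    modules = [m for m in clusters.values() if len(m) >= min_module_size]
    modules = _merge_by_eigengene(dataset.matrix, modules, merge_height)
    modules.sort(key=lambda m: (-len(m), sorted(m)[0]))

    assignments = {g: UNASSIGNED for g in genes}
    eigengenes: dict[str, pd.Series] = {}
    for i, members in enumerate(modules, start=1):
        label = f"M{i}"
        for g in members:
            assignments[g] = label
        eigengenes[label] = eigengene(dataset.matrix, members)
    return ModulePartition(dataset.dataset_id, assignments, eigengenes, tissue=dataset.tissue)


def _merge_by_eigengene(
    matrix: pd.DataFrame, modules: list[list[str]], merge_height: float
) -> list[list[str]]:
    """Iteratively merge the most correlated eigengene pair above 1 - merge_height."""
    modules = [list(m) for m in modules]
    while len(modules) > 1:
        eigs = np.array([eigengene(matrix, m).to_numpy() for m in modules])
        cors = np.corrcoef(eigs)
        np.fill_diagonal(cors, -np.inf)
        i, j = np.unravel_index(int(np.argmax(cors)), cors.shape)
        if cors[i, j] <= 1.0 - merge_height:
            break
        keep, drop = (i, j) if i < j else (j, i)
        modules[keep] = modules[keep] + modules[drop]
        del modules[drop]
    return modules


def _is_categorical(values: pd.Series) -> bool:
    return values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype) or values.dtype == bool


def mann_whitney_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact when both groups ≤ 10 and tie-free,
    otherwise normal approximation with tie and continuity correction."""
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def associate_phenotypes(
    partition: ModulePartition, phenotypes: pd.DataFrame
) -> dict[tuple[str, str], dict]:
    """Test every module eigengene against every phenotype column.

    Two-class categorical columns use a two-sided Mann–Whitney U on the
    eigengene (direction = sign of the median shift in the lexicographically
    larger level); numeric columns use a Spearman correlation test
    (direction = sign of rho).  P values are Bonferroni-corrected across the
    modules tested within each phenotype.
    """
    results: dict[tuple[str, str], dict] = {}
    for pheno in phenotypes.columns:
        values = phenotypes[pheno]
        per_pheno: list[tuple[str, dict]] = []
        for module, eig in partition.eigengenes.items():
            eig_vals = eig.reindex(values.index)
            mask = values.notna() & eig_vals.notna()
            v, e = values[mask], eig_vals[mask].to_numpy(dtype=float)
            if _is_categorical(v):
                levels = sorted(v.astype(str).unique())
                if len(levels) != 2:
                    logger.warning(
                        "phenotype %r has %d level(s); skipped", pheno, len(levels)
                    )
                    break
                a = e[(v.astype(str) == levels[0]).to_numpy()]
                b = e[(v.astype(str) == levels[1]).to_numpy()]
                if min(len(a), len(b)) < 3:
                    logger.warning("phenotype %r: group below 3 samples; skipped", pheno)
                    break
                stat, p = mann_whitney_two_sided(b, a)
                direction = float(np.sign(np.median(b) - np.median(a)))
            else:
                if mask.sum() < 5:
                    logger.warning("phenotype %r: fewer than 5 observations; skipped", pheno)
                    break
                rho, p = spearmanr(e, v.to_numpy(dtype=float))
                stat, direction = float(rho), float(np.sign(rho))
            per_pheno.append(
                (module, {"statistic": stat, "raw_p": float(p), "direction": direction})
            )
        n_tested = len(per_pheno)
        for module, res in per_pheno:
            res["bonferroni_p"] = min(1.0, res["raw_p"] * n_tested)
            results[(module, pheno)] = res
    partition.association_results.update(results)
    return results


def _d_statistic(
    x: np.ndarray, g1: np.ndarray, g2: np.ndarray, s0: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    n1, n2 = g1.sum(), g2.sum()
    m1 = x[:, g1].mean(axis=1)
    m2 = x[:, g2].mean(axis=1)
    ss1 = ((x[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    if s0 is None:
        s0 = float(np.median(s))
    return (m1 - m2) / (s + s0), s, s0


def sam_like_de(
    dataset: ExpressionDataset,
    contrast: tuple[str, str],
    group_column: str = "disease_status",
    n_permutations: int = 1000,
    seed: int | None = None,
    s0: float | None = None,
) -> DEResult:
    """Permutation d-statistic differential expression between two groups.

    ``d_i = (mean1 - mean2) / (s_i + s0)`` with pooled standard error ``s_i``
    and fudge factor ``s0`` = median of the ``s_i`` (kept fixed across
    permutations).  The null distribution of ``d`` comes from label
    permutations; each gene's q-value is the median null count of
    ``|d*| >= |d_i|`` divided by the observed count, capped at 1 and made
    monotone in ``|d|``.  When the number of distinct label arrangements is
    at most ``n_permutations``, all arrangements are enumerated instead.
    """
    labels = dataset.phenotypes[group_column].astype(str)
    g1 = (labels == contrast[0]).to_numpy()
    g2 = (labels == contrast[1]).to_numpy()
    if g1.sum() < 3 or g2.sum() < 3:
        raise ValueError(f"both groups need ≥3 samples, got {g1.sum()}/{g2.sum()}")
    x = dataset.matrix.to_numpy(dtype=float)[:, g1 | g2]
    n = x.shape[1]
    n1 = int(g1.sum())

    # reorder so group1 samples come first, simplifying permutation bookkeeping
    order = np.argsort(~g1[g1 | g2], kind="stable")
    x = x[:, order]
    base1 = np.zeros(n, dtype=bool)
    base1[:n1] = True
    d_obs, _, s0 = _d_statistic(x, base1, ~base1, s0)

    n_arrangements = math.comb(n, n1)
    rng = np.random.default_rng(seed)
    if n_arrangements <= n_permutations:
        logger.info(
            "sam_like_de: %d arrangements ≤ %d permutations; enumerating exhaustively",
            n_arrangements, n_permutations,
        )
        perms = []
        for combo in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perms.append(mask)
    else:
        perms = []
        for _ in range(n_permutations):
            idx = rng.permutation(n)[:n1]
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            perms.append(mask)

    abs_obs = np.abs(d_obs)
    null_sorted = np.empty((len(perms), x.shape[0]))
    for b, mask in enumerate(perms):
        d_b, _, _ = _d_statistic(x, mask, ~mask, s0)
        null_sorted[b] = np.sort(np.abs(d_b))

    # observed count of |d| >= t and per-permutation null counts, per gene threshold
    order_desc = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order_desc]
    obs_count = np.arange(1, len(thresholds) + 1, dtype=float)
    null_counts = np.empty((len(perms), len(thresholds)))
    for b in range(len(perms)):
        null_counts[b] = x.shape[0] - np.searchsorted(
            null_sorted[b], thresholds, side="left"
        )
    median_null = np.median(null_counts, axis=0)
    q_sorted = np.minimum(1.0, median_null / obs_count)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone non-increasing in |d|
    q = np.empty_like(q_sorted)
    q[order_desc] = q_sorted
    return DEResult(list(dataset.matrix.index), d_obs, q, contrast, len(perms))
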