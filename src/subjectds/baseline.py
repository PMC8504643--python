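"""Naive cell-level baseline: per-gene Wilcoxon rank-sum with cells as replicates.

This is the standard marker-detection recipe applied to a two-group subject
comparison: counts are depth-normalized and log-transformed, then every gene
gets a two-sided rank-sum test between the pooled cells of the two groups.
Because cells from one subject are correlated, treating them as independent
replicates (*pseudoreplication*) makes the P-values anti-conservative whenever
subject-level variance is present — the failure mode the subject-level
pseudobulk test is designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import attach_size_factors
from .ds_test import bh_adjust
from .io import CellAnnotation, CellCounts, SubjectDesign, ValidationError

DEFAULT_SCALE = 1e4


@dataclass
class NormalizedCells:
    """log1p depth-normalized expression: log(1 + scale * K_jc / s_jc)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError("identifier lists do not match matrix shape")


def normalize_log(
    cell_counts: CellCounts,
    size_factors: np.ndarray | None = None,
    scale: float = DEFAULT_SCALE,
) -> NormalizedCells:
    """Depth-normalize and log-transform: entry = log(1 + scale * K / s_jc).

    ``size_factors`` defaults to per-cell total UMIs; zero-total cells must
    have been removed (their size factor is undefined).  Zeros map to zeros,
    and scaling count and size factor together leaves entries unchanged.
    """
    if size_factors is None:
        size_factors = cell_counts.counts.sum(axis=0).astype(float)
    s = np.asarray(size_factors, float)
    if np.any(s <= 0):
        raise ValidationError("zero-total cells must be removed before normalization")
    vals = np.log1p(scale * cell_counts.counts / s[None, :])
    return NormalizedCells(list(cell_counts.genes), list(cell_counts.cells), vals)


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 50) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum P-values, rows of *x*/*y* as genes.

    Exact null enumeration when both groups are small and untied; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    small = x.shape[1] <= exact_max_n and y.shape[1] <= exact_max_n
    method = "auto" if small else "asymptotic"
    res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method=method)
    return np.atleast_1d(res.pvalue)


def run_wilcox_method(
    cell_counts: CellCounts,
    annotation: CellAnnotation,
    design: SubjectDesign,
    cell_type: str | None = None,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """The *wilcox* method: normalized/log-transformed counts, per-gene
    rank-sum test between the two groups' pooled cells, BH adjustment.

    The reported log2 fold change is the difference of group means of the
    normalized expression, divided by log 2.  Genes with zero counts in all
    selected cells are filtered (NaN pvalue/padj).
    """
    if design.group is None:
        raise ValidationError("wilcox baseline needs a two-group design")
    ann = attach_size_factors(cell_counts, annotation)
    table = ann.table
    if cell_type is not None:
        table = table[table["cell_type"] == cell_type]
        if table.empty:
            raise ValidationError(f"no cells with cell_type {cell_type!r}")

    group_of = dict(zip(design.subject_ids, design.group))
    levels = list(dict.fromkeys(design.group))
    cell_group = table["subject_id"].map(group_of)
    if cell_group.isna().any():
        raise ValidationError("annotation references subjects not in design")
    col_of = {c: k for k, c in enumerate(cell_counts.cells)}
    cols1 = [col_of[c] for c in table.loc[cell_group == levels[0], "cell_id"]]
    cols2 = [col_of[c] for c in table.loc[cell_group == levels[1], "cell_id"]]
    if not cols1 or not cols2:
        raise ValidationError("each group needs at least one cell")

    sf = np.zeros(cell_counts.n_cells)
    sf[[col_of[c] for c in table["cell_id"]]] = table["size_factor"].to_numpy(float)
    keep_cols = cols1 + cols2
    sub = CellCounts(
        list(cell_counts.genes),
        [cell_counts.cells[k] for k in keep_cols],
        cell_counts.counts[:, keep_cols],
    )
    norm = normalize_log(sub, sf[keep_cols], scale=scale)
    n1 = len(cols1)
    v1, v2 = norm.values[:, :n1], norm.values[:, n1:]

    tested = sub.counts.sum(axis=1) > 0
    res = pd.DataFrame(
        {
            "gene": sub.genes,
            "baseMean": norm.values.mean(axis=1),
            "log2FoldChange": (v2.mean(axis=1) - v1.mean(axis=1)) / np.log(2.0),
            "stat": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
            "status": np.where(tested, "ok", "filtered_all_zero"),
        }
    )
    if tested.any():
        p = rank_sum_test(v1[tested], v2[tested])
        res.loc[tested, "pvalue"] = p
        res.loc[tested, "padj"] = bh_adjust(p)
    return res
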