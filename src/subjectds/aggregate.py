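"""Pseudobulk aggregation: collapse gene-by-cell counts to gene-by-subject counts.

Within one cell type, the aggregated count for gene *i* and subject *j* is
``K_ij = sum_c K_ijc`` over the subject's cells, and the subject size factor
is the matching sum ``s_j = sum_c s_jc``.  The resulting table has the mean
and (for many cells per subject) the variance structure of a bulk RNA-seq
experiment, so it can be handed to any negative-binomial bulk engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellAnnotation, CellCounts, SubjectDesign, ValidationError, validate_pair

log = logging.getLogger(__name__)


@dataclass
class PseudobulkCounts:
    """Gene-by-subject aggregated counts with per-subject size factors."""

    genes: list[str]
    subjects: list[str]
    counts: np.ndarray  # (G, n) integer
    size_factors: np.ndarray  # (n,) > 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.size_factors = np.asarray(self.size_factors, float)
        g, n = self.counts.shape
        if len(self.genes) != g or len(self.subjects) != n:
            raise ValidationError("identifier lists do not match matrix shape")
        if self.size_factors.shape != (n,):
            raise ValidationError("one size factor per subject required")
        if np.any(self.size_factors <= 0):
            raise ValidationError("subject size factors must be > 0")
        if np.any(self.counts < 0):
            raise ValidationError("negative aggregated counts")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.subjects)


def compute_size_factors(cell_counts: CellCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell size factors s_jc as total UMIs (column sums).

    Returns ``(size_factors, zero_mask)`` where ``zero_mask`` flags cells with
    zero total count; those must be removed before aggregation because a size
    factor of 0 is undefined.
    """
    sf = cell_counts.counts.sum(axis=0).astype(float)
    return sf, sf == 0


def attach_size_factors(cell_counts: CellCounts, annotation: CellAnnotation) -> CellAnnotation:
    """Fill the annotation's size_factor column from total UMIs when absent,
    dropping zero-count cells (and their annotation rows)."""
    ann = annotation.aligned_to(cell_counts)
    if not ann.size_factors_pending:
        return ann
    sf, zero = compute_size_factors(cell_counts)
    if zero.any():
        log.warning("dropping %d zero-count cells before size-factor assignment", zero.sum())
    table = ann.table.loc[~zero].copy()
    table["size_factor"] = sf[~zero]
    return CellAnnotation(table)


def aggregate_counts(
    cell_counts: CellCounts,
    annotation: CellAnnotation,
    cell_type: str | None = None,
    subject_order: list[str] | None = None,
) -> PseudobulkCounts:
    """Sum counts over each subject's cells of the given type.

    Cells with zero total count are excluded first.  Subjects with no selected
    cells are omitted from the output (with a warning) rather than zero-filled.
    ``subject_order`` (e.g. from a :class:`SubjectDesign`) fixes the column
    order; by default subjects appear in annotation order.
    """
    validate_pair(cell_counts, annotation)
    ann = attach_size_factors(cell_counts, annotation)
    table = ann.table
    if cell_type is not None:
        table = table[table["cell_type"] == cell_type]
        if table.empty:
            raise ValidationError(f"no cells with cell_type {cell_type!r}")

    col_of = {c: k for k, c in enumerate(cell_counts.cells)}
    subjects_present = list(dict.fromkeys(table["subject_id"]))
    if subject_order is not None:
        dropped = [s for s in subject_order if s not in subjects_present]
        if dropped:
            log.warning("subjects with no selected cells omitted: %s", dropped)
        subjects = [s for s in subject_order if s in subjects_present]
        extra = [s for s in subjects_present if s not in subject_order]
        if extra:
            raise ValidationError(f"annotation references subjects not in design: {extra}")
    else:
        subjects = subjects_present

    K = np.zeros((cell_counts.n_genes, len(subjects)), dtype=np.int64)
    s = np.zeros(len(subjects))
    for k, subj in enumerate(subjects):
        rows = table[table["subject_id"] == subj]
        cols = [col_of[c] for c in rows["cell_id"]]
        K[:, k] = cell_counts.counts[:, cols].sum(axis=1)
        s[k] = rows["size_factor"].sum()
    return PseudobulkCounts(list(cell_counts.genes), subjects, K, s)


def pseudobulk_for_design(
    cell_counts: CellCounts,
    annotation: CellAnnotation,
    design: SubjectDesign,
    cell_type: str | None = None,
) -> tuple[PseudobulkCounts, SubjectDesign]:
    """Aggregate and subset the design to the subjects that have cells,
    keeping design row order for the pseudobulk columns."""
    pb = aggregate_counts(cell_counts, annotation, cell_type, subject_order=design.subject_ids)
    if pb.subjects != design.subject_ids:
        keep = [design.subject_ids.index(s) for s in pb.subjects]
        design = SubjectDesign(
            pb.subjects,
            design.covariates[keep],
            design.covariate_names,
            [design.group[i] for i in keep] if design.group is not None else None,
        )
    return pb, design


def write_pseudobulk(pb: PseudobulkCounts, counts_path: str, sf_path: str) -> None:
    """Pseudobulk TSV (genes x subjects) plus a subject size-factor sidecar."""
    pb.to_frame().to_csv(counts_path, sep="\t")
    pd.DataFrame({"subject_id": pb.subjects, "size_factor": pb.size_factors}).to_csv(
        sf_path, sep="\t", index=False, float_format="%.12g"
    )
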