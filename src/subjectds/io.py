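"""Readers, writers and validated containers for counts, cell metadata and results.

The on-disk formats are the ones single-cell pipelines already exchange:
MatrixMarket coordinate matrices with ``features.tsv``/``barcodes.tsv``
sidecars (genes as rows, 1-based indices, the CellRanger convention), dense
CSV/TSV count tables (header row = cell identifiers), and plain TSV metadata
and result tables.  Gene and cell identifiers are opaque strings; nothing in
this package interprets genome coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant or cross-reference."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CellCounts:
    """Gene-by-cell UMI count matrix.

    ``counts[i, c]`` is the number of molecules of gene ``genes[i]`` observed
    in cell ``cells[c]``.  Entries must be non-negative integers; identifier
    lists must be unique and match the matrix dimensions.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        g, c = self.counts.shape
        if len(self.genes) != g or len(self.cells) != c:
            raise ValidationError(
                f"identifier lists ({len(self.genes)} genes, {len(self.cells)} cells) "
                f"do not match matrix shape {self.counts.shape}"
            )
        if len(set(self.genes)) != g:
            raise ValidationError("gene identifiers are not unique")
        if len(set(self.cells)) != c:
            raise ValidationError("cell identifiers are not unique")
        if self.counts.size:
            if np.any(self.counts < 0):
                raise ValidationError("negative count entries")
            if not np.issubdtype(self.counts.dtype, np.integer):
                if np.any(self.counts != np.floor(self.counts)):
                    raise ValidationError("non-integer count entries")
                self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class CellAnnotation:
    """Per-cell subject assignment, cell-type label and size factor.

    The size factor ``s_jc`` scales the Poisson sampling stage; its simple
    default is the total UMI count of the cell, filled in by
    :func:`subjectds.aggregate.compute_size_factors` when absent
    (``size_factors_pending`` is then True).
    """

    table: pd.DataFrame

    REQUIRED = ("cell_id", "subject_id", "cell_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing required columns: {missing}")
        dup = self.table["cell_id"][self.table["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated cell_id rows: {sorted(set(dup))}")
        if "size_factor" in self.table.columns:
            sf = self.table["size_factor"].to_numpy(float)
            if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
                raise ValidationError("size factors must be finite and > 0")
        self.table = self.table.reset_index(drop=True)

    @property
    def size_factors_pending(self) -> bool:
        return "size_factor" not in self.table.columns

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    @property
    def subject_ids(self) -> list[str]:
        """Distinct subjects in first-appearance order."""
        return list(dict.fromkeys(self.table["subject_id"]))

    def aligned_to(self, counts: CellCounts) -> "CellAnnotation":
        """Reorder rows to the cell order of *counts*; cell sets must match."""
        validate_pair(counts, self)
        idx = self.table.set_index("cell_id").loc[counts.cells].reset_index()
        return CellAnnotation(idx)


@dataclass
class SubjectDesign:
    """Per-subject covariate rows for the regression log q_ij = sum_r x_jr b_ir.

    In the simple two-group design the covariates are an intercept column of
    ones and a group-2 indicator; ``group`` keeps the original labels.
    """

    subject_ids: list[str]
    covariates: np.ndarray  # (n_subjects, R)
    covariate_names: list[str] = field(default_factory=list)
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
        n, r = self.covariates.shape
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids do not match covariate rows")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject_id rows")
        if not self.covariate_names:
            self.covariate_names = [f"x{k + 1}" for k in range(r)]
        if self.group is not None and len(self.group) != n:
            raise ValidationError("group labels do not match subject rows")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_groups(cls, subject_ids: list[str], group: list[str]) -> "SubjectDesign":
        """Intercept + group-indicator design from a two-level label vector."""
        levels = list(dict.fromkeys(group))
        if len(levels) != 2:
            raise ValidationError(f"expected exactly two group levels, got {levels}")
        x2 = np.array([g == levels[1] for g in group], float)
        X = np.column_stack([np.ones(len(group)), x2])
        return cls(list(subject_ids), X, ["intercept", f"group[{levels[1]}]"], list(group))

    def relabeled(self, group: list[str]) -> "SubjectDesign":
        """Same subjects with permuted group labels (for permutation tests)."""
        return SubjectDesign.from_groups(self.subject_ids, group)


def validate_pair(counts: CellCounts, annotation: CellAnnotation) -> None:
    """Reject a counts/annotation pair whose cell sets differ."""
    mat_cells = set(counts.cells)
    ann_cells = set(annotation.table["cell_id"])
    extra = sorted(ann_cells - mat_cells)
    miss = sorted(mat_cells - ann_cells)
    if extra or miss:
        raise ValidationError(
            f"counts/annotation cell sets differ: "
            f"{len(miss)} unannotated (e.g. {miss[:5]}), "
            f"{len(extra)} unknown (e.g. {extra[:5]})"
        )


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------

def read_counts(path: str, format: str | None = None) -> CellCounts:
    """Read a gene-by-cell count matrix.

    ``format`` is one of ``mtx``, ``csv``, ``tsv``; inferred from the file
    extension when omitted.  For MTX, ``features.tsv`` and ``barcodes.tsv``
    sidecars in the same directory supply the identifiers (first column).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lstrip(".").lower()
        format = ext if ext in ("mtx", "csv", "tsv") else None
    if format not in ("mtx", "csv", "tsv"):
        raise FormatError(f"unknown counts format for {path!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "mtx":
        return _read_mtx(path)
    sep = "," if format == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    mat = df.to_numpy()
    if mat.size and not np.issubdtype(mat.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count table")
    try:
        return CellCounts(list(df.index.astype(str)), list(df.columns.astype(str)), mat)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_mtx(path: str) -> CellCounts:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    d = os.path.dirname(os.path.abspath(path))
    genes = _read_sidecar(os.path.join(d, "features.tsv"), dense.shape[0], "gene")
    cells = _read_sidecar(os.path.join(d, "barcodes.tsv"), dense.shape[1], "cell")
    try:
        return CellCounts(genes, cells, dense)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_sidecar(path: str, n: int, what: str) -> list[str]:
    if not os.path.exists(path):
        return [f"{what}{k + 1}" for k in range(n)]
    names = [line.split("\t")[0].strip() for line in open(path) if line.strip()]
    if len(names) != n:
        raise FormatError(
            f"{path}: {len(names)} {what} identifiers for a matrix with {n} {what} rows"
        )
    return names


def write_counts(counts: CellCounts, path: str, format: str | None = None) -> None:
    """Write counts as MTX (+ sidecars) or a dense CSV/TSV table."""
    if format is None:
        ext = os.path.splitext(path)[1].lstrip(".").lower()
        format = ext if ext in ("mtx", "csv", "tsv") else "tsv"
    if format == "mtx":
        sp = scipy.sparse.coo_matrix(counts.counts)
        scipy.io.mmwrite(path, sp, field="integer")
        d = os.path.dirname(os.path.abspath(path))
        with open(os.path.join(d, "features.tsv"), "w") as fh:
            fh.write("".join(f"{g}\n" for g in counts.genes))
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("".join(f"{c}\n" for c in counts.cells))
        return
    sep = "," if format == "csv" else "\t"
    pd.DataFrame(counts.counts, index=counts.genes, columns=counts.cells).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

def read_annotation(path: str) -> CellAnnotation:
    """Read per-cell metadata TSV (cell_id, subject_id, cell_type[, size_factor])."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "subject_id": str})
    try:
        return CellAnnotation(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_annotation(annotation: CellAnnotation, path: str) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_subjects(path: str, group_col: str = "group") -> SubjectDesign:
    """Read per-subject metadata TSV with a subject_id column and a two-level
    group column; builds the intercept + indicator design."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise ValidationError(f"{path}: no subject_id column")
    if group_col not in df.columns:
        raise ValidationError(f"{path}: no {group_col!r} column")
    return SubjectDesign.from_groups(list(df["subject_id"]), list(df[group_col]))


def write_subjects(design: SubjectDesign, path: str, group_col: str = "group") -> None:
    if design.group is None:
        raise ValidationError("design has no group labels to write")
    pd.DataFrame({"subject_id": design.subject_ids, group_col: design.group}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["gene", "baseMean", "log2FoldChange", "stat", "pvalue", "padj"]


def write_results(ds_result: pd.DataFrame, path: str) -> None:
    """Write a differential-state result table as TSV.

    Expects the columns of :data:`RESULT_COLUMNS`; genes filtered before
    testing carry empty ``pvalue``/``padj`` fields.  Row order is the input
    gene order; floats keep 12 significant digits so a read-back round trip
    is lossless at that precision.
    """
    missing = [c for c in RESULT_COLUMNS if c not in ds_result.columns]
    if missing:
        raise ValidationError(f"result table missing columns: {missing}")
    out = ds_result[RESULT_COLUMNS + [c for c in ds_result.columns if c not in RESULT_COLUMNS]]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df
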