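"""Exhaustive label-permutation calibration of differential-state P-values.

With few subjects, all distinct reassignments of the two group labels can be
enumerated (7 subjects split 4/3 gives C(7,4) = 35).  Re-running a DS method
under every relabeling and ranking the observed per-gene P-value among the
permuted ones yields *permutation P-values* whose distribution is calibrated
by construction; comparing their empirical CDF with that of the method's own
P-values diagnoses anti-conservative methods (the method CDF racing ahead of
the permutation CDF on small P-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable

import numpy as np
import pandas as pd

from .io import SubjectDesign, ValidationError

MAX_EXHAUSTIVE_SUBJECTS = 20


@dataclass
class PermutationScheme:
    """All distinct two-group label assignments over the given subjects.

    Each assignment lists the subjects placed in group 1 (size n1); there are
    C(n, n1) of them.  With equal group sizes, mirrored assignments are
    distinct labelings but yield identical P-values for the (symmetric)
    two-sided tests in this package.
    """

    subject_ids: list[str]
    n1: int
    assignments: list[tuple[str, ...]]

    @property
    def n_assignments(self) -> int:
        return len(self.assignments)

    def group_labels(self, assignment: tuple[str, ...], levels: tuple[str, str] = ("group1", "group2")) -> list[str]:
        in1 = set(assignment)
        return [levels[0] if s in in1 else levels[1] for s in self.subject_ids]


def enumerate_assignments(subject_ids: list[str], n1: int) -> PermutationScheme:
    """Enumerate the C(n, n1) subject subsets forming group 1, in
    lexicographic (input-order) sequence.

    Guarded at 20 subjects; beyond that, subsample assignments Monte-Carlo
    style instead of enumerating.
    """
    n = len(subject_ids)
    if not 0 < n1 < n:
        raise ValidationError("group size n1 must satisfy 0 < n1 < n_subjects")
    if len(set(subject_ids)) != n:
        raise ValidationError("duplicate subject ids")
    if n > MAX_EXHAUSTIVE_SUBJECTS:
        raise ValidationError(
            f"{n} subjects gives {comb(n, n1)} assignments; exhaustive enumeration "
            f"is guarded at {MAX_EXHAUSTIVE_SUBJECTS} subjects - use Monte-Carlo subsampling"
        )
    assignments = [tuple(c) for c in combinations(subject_ids, n1)]
    return PermutationScheme(list(subject_ids), n1, assignments)


@dataclass
class CalibrationResult:
    """Observed method P-values and their permutation P-values, per gene."""

    genes: list[str]
    observed_p: np.ndarray
    permutation_p: np.ndarray
    n_assignments: int
    failed: np.ndarray  # genes excluded (method failure on some assignment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "method_pvalue": self.observed_p,
                "permutation_pvalue": self.permutation_p,
                "excluded": self.failed.astype(int),
            }
        )


MethodRunner = Callable[[SubjectDesign], pd.DataFrame]


def permutation_pvalues(
    method_runner: MethodRunner,
    design: SubjectDesign,
    scheme: PermutationScheme | None = None,
) -> CalibrationResult:
    """Permutation P-values for a DS method under exhaustive relabeling.

    ``method_runner(design)`` must return a result table with ``gene`` and
    ``pvalue`` columns and be deterministic given the labels.  The permutation
    test statistic is the method's unadjusted P-value; for each gene the
    permutation P-value is the proportion of assignments (observed labeling
    included) whose statistic is <= the observed one.
    """
    if design.group is None:
        raise ValidationError("permutation calibration needs group labels")
    levels = tuple(dict.fromkeys(design.group))
    if scheme is None:
        n1 = design.group.count(levels[0])
        scheme = enumerate_assignments(design.subject_ids, n1)

    observed = method_runner(design)
    genes = list(observed["gene"])
    obs_p = observed["pvalue"].to_numpy(float)
    failed = ~np.isfinite(obs_p)

    n_le = np.zeros(len(genes))
    observed_set = frozenset(np.array(design.subject_ids)[np.array(design.group) == levels[0]])
    saw_observed = False
    for assignment in scheme.assignments:
        if frozenset(assignment) == observed_set:
            perm_p = obs_p
            saw_observed = True
        else:
            labels = scheme.group_labels(assignment, levels)
            res = method_runner(design.relabeled(labels))
            if list(res["gene"]) != genes:
                raise ValidationError("method returned inconsistent gene lists across assignments")
            perm_p = res["pvalue"].to_numpy(float)
        failed |= ~np.isfinite(perm_p)
        n_le += perm_p <= obs_p
    if not saw_observed:
        raise ValidationError("observed labeling is not among the enumerated assignments")

    perm_pvals = n_le / scheme.n_assignments
    perm_pvals[failed] = np.nan
    return CalibrationResult(genes, obs_p, perm_pvals, scheme.n_assignments, failed)


def cdf_compare(
    result: CalibrationResult, grid: np.ndarray | None = None, gap_range: tuple[float, float] = (0.0, 0.2)
) -> tuple[pd.DataFrame, float]:
    """Empirical CDFs of method and permutation P-values on a shared grid.

    Returns the CDF table and the maximum absolute CDF gap over
    ``gap_range`` (default [0, 0.2], where anti-conservative inflation shows).
    """
    keep = ~result.failed
    if not keep.any():
        raise ValidationError("no genes with both method and permutation P-values")
    obs = result.observed_p[keep]
    perm = result.permutation_p[keep]
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(grid, float)
    cdf_m = np.searchsorted(np.sort(obs), grid, side="right") / obs.size
    cdf_p = np.searchsorted(np.sort(perm), grid, side="right") / perm.size
    table = pd.DataFrame({"p": grid, "method_cdf": cdf_m, "permutation_cdf": cdf_p})
    lo, hi = gap_range
    sel = (grid >= lo) & (grid <= hi)
    gap = float(np.max(np.abs(cdf_m[sel] - cdf_p[sel]))) if sel.any() else 0.0
    return table, gap
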