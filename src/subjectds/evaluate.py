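"""Detection-performance metrics for simulated differential-state studies.

A method's adjusted P-values are thresholded over a grid of cutoffs; against
the simulation truth this yields precision-recall and ROC curves, their areas
(AUPR by step-wise interpolation, AUROC by trapezoid, equal to the
tie-corrected Mann-Whitney concordance statistic), and the confusion-table
rates PPV, NPV, TPR, FPR at a single cutoff (0.05 by convention).  Curves
from replicate simulations are vertically averaged on a fixed recall grid.

Detection uses the strict rule ``padj < cutoff``.  Genes without an adjusted
P-value (filtered before testing) are treated as never detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

RECALL_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def _prep(adjusted_p: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(adjusted_p, float)
    t = np.asarray(truth, bool)
    if p.shape != t.shape:
        raise ValidationError("adjusted P-values and truth flags must align")
    p = np.where(np.isnan(p), np.inf, p)  # filtered genes: never detected
    return p, t


def _detection_counts(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cutoff grid (distinct adjusted P-values plus {0, 1}) with the number of
    detections and true detections strictly below each cutoff; the closing
    cutoff-1 point detects every tested (finite-padj) gene, so curves end at
    the detect-all corner even when the largest P-value is tied."""
    finite = p[np.isfinite(p)]
    cuts = np.unique(np.concatenate([[0.0], finite, [1.0]]))
    order = np.argsort(p, kind="stable")
    ps, ts = p[order], t[order]
    n_det = np.searchsorted(ps, cuts, side="left")
    tp = np.concatenate([[0], np.cumsum(ts)])[n_det]
    # closing point: everything tested is detected
    n_all = finite.size
    tp_all = int(t[np.isfinite(p)].sum())
    if n_det[-1] != n_all or tp[-1] != tp_all:
        cuts = np.append(cuts, 1.0)
        n_det = np.append(n_det, n_all)
        tp = np.append(tp, tp_all)
    return cuts, n_det, tp


def pr_curve(adjusted_p: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision and recall over the cutoff grid of distinct adjusted P-values.

    At cutoff t, detected = {padj < t}; precision = |detected & DE|/|detected|
    (1 when nothing is detected, the standard PR convention) and
    recall = |detected & DE|/|DE|.  Requires at least one truly DE gene.
    """
    p, t = _prep(adjusted_p, truth)
    n_de = int(t.sum())
    if n_de == 0:
        raise ValidationError("no differentially expressed genes in truth: recall undefined")
    cuts, n_det, tp = _detection_counts(p, t)
    with np.errstate(invalid="ignore"):
        precision = np.where(n_det > 0, tp / np.maximum(n_det, 1), 1.0)
    recall = tp / n_de
    return cuts, precision, recall


def aupr(adjusted_p: np.ndarray, truth: np.ndarray) -> float:
    """Area under the PR curve with step-wise interpolation (precision held
    at the value achieved at the next attained recall level)."""
    _, precision, recall = pr_curve(adjusted_p, truth)
    area = 0.0
    for k in range(1, len(recall)):
        area += (recall[k] - recall[k - 1]) * precision[k]
    return float(area)


def roc_curve(adjusted_p: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """TPR and FPR over the cutoff grid; needs >= 1 DE and >= 1 null gene."""
    p, t = _prep(adjusted_p, truth)
    n_de, n_null = int(t.sum()), int((~t).sum())
    if n_de == 0:
        raise ValidationError("no differentially expressed genes in truth")
    if n_null == 0:
        raise ValidationError("no null genes in truth: FPR undefined")
    cuts, n_det, tp = _detection_counts(p, t)
    fp = n_det - tp
    return cuts, fp / n_null, tp / n_de


def auroc(adjusted_p: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Ties in adjusted P-values enter as diagonal segments, so the value equals
    the tie-corrected Mann-Whitney concordance probability
    P(p_DE < p_null) + 0.5 P(tie).
    """
    _, fpr, tpr = roc_curve(adjusted_p, truth)
    return float(np.trapezoid(tpr, fpr))


NOT_COMPUTABLE = float("nan")


def confusion_at_cutoff(
    adjusted_p: np.ndarray, truth: np.ndarray, cutoff: float = 0.05
) -> dict[str, float]:
    """PPV, NPV, TPR, FPR (and FDR = 1 - PPV) for detection padj < cutoff.

    Ratios with empty denominators (e.g. PPV when nothing is detected) are
    returned as NaN, never silently 0.
    """
    if not 0 < cutoff < 1:
        raise ValidationError("cutoff must lie in (0, 1)")
    p, t = _prep(adjusted_p, truth)
    det = p < cutoff
    tp = int((det & t).sum())
    fp = int((det & ~t).sum())
    fn = int((~det & t).sum())
    tn = int((~det & ~t).sum())
    ppv = tp / (tp + fp) if tp + fp else NOT_COMPUTABLE
    npv = tn / (tn + fn) if tn + fn else NOT_COMPUTABLE
    tpr = tp / (tp + fn) if tp + fn else NOT_COMPUTABLE
    fpr = fp / (fp + tn) if fp + tn else NOT_COMPUTABLE
    fdr = fp / (tp + fp) if tp + fp else NOT_COMPUTABLE
    return {"PPV": ppv, "NPV": npv, "TPR": tpr, "FPR": fpr, "FDR": fdr, "n_detected": tp + fp}


@dataclass
class EvalSummary:
    """Metrics for one replicate of one simulation setting."""

    replicate: int
    aupr: float
    auroc: float
    confusion: dict[str, float]
    precision_on_grid: np.ndarray  # precision at RECALL_GRID (vertical averaging)

    def to_row(self) -> dict:
        row = {"replicate": self.replicate, "AUPR": self.aupr, "AUROC": self.auroc}
        row.update(self.confusion)
        return row


def summarize_replicate(
    adjusted_p: np.ndarray, truth: np.ndarray, replicate: int = 0, cutoff: float = 0.05
) -> EvalSummary:
    cuts, precision, recall = pr_curve(adjusted_p, truth)
    return EvalSummary(
        replicate=replicate,
        aupr=aupr(adjusted_p, truth),
        auroc=auroc(adjusted_p, truth),
        confusion=confusion_at_cutoff(adjusted_p, truth, cutoff),
        precision_on_grid=interpolate_precision(precision, recall),
    )


def interpolate_precision(precision: np.ndarray, recall: np.ndarray, grid: np.ndarray = RECALL_GRID) -> np.ndarray:
    """Step-wise precision at each grid recall: the precision achieved at the
    smallest attained recall >= the grid point (carried from the right)."""
    out = np.empty(grid.size)
    for k, r in enumerate(grid):
        ge = recall >= r
        out[k] = precision[np.argmax(ge)] if ge.any() else precision[-1]
    return out


def average_curves(per_replicate: list[EvalSummary]) -> pd.DataFrame:
    """Vertical averaging: mean precision at each recall grid point, with the
    mean AUPR attached as a column (mean of per-replicate areas)."""
    if not per_replicate:
        raise ValidationError("need at least one replicate")
    prec = np.vstack([s.precision_on_grid for s in per_replicate])
    return pd.DataFrame(
        {
            "recall": RECALL_GRID,
            "mean_precision": prec.mean(axis=0),
            "mean_AUPR": np.mean([s.aupr for s in per_replicate]),
        }
    )


def summary_table(per_replicate: list[EvalSummary]) -> pd.DataFrame:
    """Per-replicate metric rows plus a 'mean' row (NaN-aware averaging)."""
    rows = pd.DataFrame([s.to_row() for s in per_replicate])
    mean = rows.drop(columns="replicate").mean(skipna=True)
    mean["replicate"] = "mean"
    return pd.concat([rows, mean.to_frame().T], ignore_index=True)
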