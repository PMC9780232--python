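"""Balanced scoring of DE results against simulated ground truth.

The headline score is the Matthews correlation coefficient, a confusion-matrix
summary in [-1, 1] that only rewards a method performing well on both the DE
and the non-DE genes, complemented by type-1 error at a fixed p-value cutoff
and by ROC curves for power comparison at matched test size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import sklearn.metrics

from .simulate import GeneTruth

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "confusion_at_alpha",
    "mcc",
    "type1_error",
    "sensitivity",
    "roc_curve",
    "sensitivity_at_fpr",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    alpha: float
    n_missing: int = 0

    @property
    def n_genes(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.n_missing


@dataclass
class ROCCurve:
    """Ordered (FPR, TPR) pairs from (0,0) to (1,1) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion_at_alpha(p_values: np.ndarray, truth: GeneTruth,
                       alpha: float) -> ConfusionCounts:
    """Tally the confusion matrix of 'p <= alpha' calls against truth.

    The boundary is inclusive (p = alpha is a positive call).  Genes with
    missing p-values are excluded from the counts and reported separately.
    """
    p = np.asarray(p_values, dtype=float)
    if p.shape != truth.is_de.shape:
        raise ValueError("p_values and truth must have the same length")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    valid = np.isfinite(p)
    called = valid & (p <= alpha)
    de = truth.is_de
    return ConfusionCounts(
        tp=int(np.sum(called & de)),
        fp=int(np.sum(called & ~de)),
        tn=int(np.sum(valid & ~called & ~de)),
        fn=int(np.sum(valid & ~called & de)),
        alpha=alpha,
        n_missing=int(np.sum(~valid)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal is zero."""
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def type1_error(c: ConfusionCounts) -> float:
    """False-positive rate among truly null genes, fp / (fp + tn)."""
    denom = c.fp + c.tn
    return float("nan") if denom == 0 else c.fp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate among truly DE genes, tp / (tp + fn)."""
    denom = c.tp + c.fn
    return float("nan") if denom == 0 else c.tp / denom


def roc_curve(p_values: np.ndarray, is_de: np.ndarray) -> ROCCurve:
    """ROC of the 'small p-value means DE' ranking against truth.

    The threshold sweeps the unique p-values (ties form a single point);
    the curve is anchored at (0,0) and (1,1) and genes with missing p are
    dropped.  AUC is the trapezoidal integral.
    """
    p = np.asarray(p_values, dtype=float)
    de = np.asarray(is_de, dtype=bool)
    valid = np.isfinite(p)
    p, de = p[valid], de[valid]
    if de.all() or not de.any():
        raise ValueError("need at least one DE and one non-DE gene with a p-value")
    # score -p: 'score >= threshold' reproduces the inclusive p <= alpha call
    fpr, tpr, _ = sklearn.metrics.roc_curve(de, -p, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
    auc = float(sklearn.metrics.auc(fpr, tpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def sensitivity_at_fpr(curve: ROCCurve, target_fpr: float) -> float:
    """TPR at a fixed FPR, linearly interpolated between bracketing ROC points.

    Where the empirical curve is vertical (several TPRs at one FPR), the
    highest attained TPR at that FPR is used.
    """
    if not 0.0 < target_fpr < 1.0:
        raise ValueError("target_fpr must lie in (0, 1)")
    fpr, tpr = curve.fpr, curve.tpr
    # collapse vertical segments: max tpr per unique fpr (fpr is sorted)
    uniq, idx = np.unique(fpr, return_index=True)
    tpr_u = np.maximum.reduceat(tpr, idx)
    return float(np.interp(target_fpr, uniq, tpr_u))
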