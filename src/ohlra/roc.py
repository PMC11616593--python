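"""ROC analysis of the OHLRA score against dichotomized hearing loss.

Risk cut-offs are derived by dichotomizing hearing loss at 25, 40 and 60 dB
HL (positive class: strictly above the threshold), building the empirical
ROC curve of the OHLRA score, and selecting the operating point closest to
the ideal corner (FPR 0, TPR 1) in Euclidean distance.  The returned score
threshold is the midpoint between the adjacent distinct scores straddling
that operating point, so categorizing the training data reproduces the
operating point exactly.  AUC is the Mann-Whitney pair statistic; its 95%
confidence interval uses the Hanley-McNeil standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .index import CutoffSet

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "empirical_roc",
    "auc",
    "auc_ci",
    "optimal_cutoff",
    "derive_risk_cutoffs",
    "DEFAULT_HL_THRESHOLDS",
]

DEFAULT_HL_THRESHOLDS = (25.0, 40.0, 60.0)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: descending score thresholds with parallel FPR/TPR arrays."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing along the curve")


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels must contain both classes")


def empirical_roc(scores, labels) -> RocCurve:
    """Standard empirical ROC over all distinct score thresholds (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    return float(roc_auc_score(labels, scores))


def auc_ci(auc_value: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley-McNeil 95% confidence interval for an AUC estimate."""
    a = float(auc_value)
    if not 0 <= a <= 1:
        raise ValueError("auc must lie in [0, 1]")
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = float(np.sqrt(max(var, 0.0)))
    return (max(a - 1.96 * se, 0.0), min(a + 1.96 * se, 1.0))


def optimal_cutoff(curve: RocCurve) -> OperatingPoint:
    """Operating point minimizing the distance sqrt((1-TPR)^2 + FPR^2) to (0, 1).

    Ties are broken toward the lower score threshold.  The returned
    threshold is the midpoint between the adjacent distinct scores
    straddling the operating point (the curve's thresholds are the distinct
    scores in descending order), so "score above the cut-off" reproduces
    the operating point on the data that produced the curve.
    """
    dist2 = (1 - curve.tpr) ** 2 + curve.fpr**2
    # argmin scans in descending-threshold order; keep the LAST minimal entry
    # (lowest threshold) on ties
    best = int(len(dist2) - 1 - np.argmin(dist2[::-1]))
    thr = float(curve.thresholds[best])
    sens = float(curve.tpr[best])
    spec = float(1 - curve.fpr[best])
    if np.allclose(curve.tpr, curve.fpr):
        warnings.warn("degenerate (diagonal) ROC curve: cut-off is arbitrary", stacklevel=2)
    if best + 1 < len(curve.thresholds):
        thr = (thr + float(curve.thresholds[best + 1])) / 2 if np.isfinite(thr) else float(
            curve.thresholds[best + 1]
        )
    elif not np.isfinite(thr):  # single-point degenerate curve
        thr = 0.0
    return OperatingPoint(threshold=thr, sensitivity=sens, specificity=spec)


def derive_risk_cutoffs(
    cohort: pd.DataFrame,
    hl_thresholds=DEFAULT_HL_THRESHOLDS,
    score_col: str = "ohlra_score",
    hl_col: str = "hearing_loss_dB",
) -> CutoffSet:
    """ROC-derived risk cut-offs for each hearing-loss threshold.

    For each threshold t the positive class is hearing loss strictly above
    t; the closest-to-ideal cut-off, its sensitivity/specificity, and the
    AUC with Hanley-McNeil 95% CI are computed.  Warns (not errors) if the
    cut-offs are not strictly increasing.
    """
    for col in (score_col, hl_col):
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing column {col!r}")
    scores = cohort[score_col].to_numpy(dtype=float)
    hl = cohort[hl_col].to_numpy(dtype=float)

    cuts, sens, spec, aucs, cis = [], [], [], [], []
    for t in hl_thresholds:
        labels = (hl > t).astype(int)
        if labels.min() == labels.max():
            raise ValueError(f"dichotomization at {t} dB yields a single class")
        curve = empirical_roc(scores, labels)
        op = optimal_cutoff(curve)
        a = auc(scores, labels)
        cuts.append(op.threshold)
        sens.append(op.sensitivity)
        spec.append(op.specificity)
        aucs.append(a)
        cis.append(auc_ci(a, int(labels.sum()), int((1 - labels).sum())))
    if not (cuts[0] < cuts[1] < cuts[2] if len(cuts) == 3 else all(np.diff(cuts) > 0)):
        warnings.warn(f"derived cut-offs are not strictly increasing: {cuts}", stacklevel=2)
    return CutoffSet(
        t_low_mod=cuts[0], t_mod_high=cuts[1], t_high_vhigh=cuts[2],
        sensitivity=tuple(sens), specificity=tuple(spec),
        auc=tuple(aucs), auc_ci=tuple(cis),
    )
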