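"""The OHLRA index: weighted sum of the nine item scores, and risk categories.

OHLRA = C1*A + C2*WE + C3*S + C4*D + C5*ON + C6*LN + C7*UPPE + C8*NRR + C9*APPE

The default weights are the indirect-effect coefficients of the published
three-factor path model (age 0.266, work experience 0.227, smoking 0.056,
diseases 0.064, occupational noise 0.687, leisure noise 0.660, PPE use 0.194,
NRR 0.147, PPE awareness 0.127).  With those weights the attainable score
range is [1.2864, 12.14].

Scores are mapped to four risk levels by three ROC-derived cut-offs; the
published values are 4.85 / 6.84 / 7.59 and boundary scores belong to the
higher category (a score of exactly 4.85 is Moderate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

from .rubric import ItemScoreVector

__all__ = [
    "CoefficientSet",
    "CutoffSet",
    "RiskCategory",
    "OhlraAssessment",
    "DEFAULT_COEFFICIENTS",
    "PAPER_CUTOFFS",
    "compute_ohlra",
    "categorize",
    "score_range",
]


class RiskCategory(str, Enum):
    LOW = "Low"
    MODERATE = "Moderate"
    HIGH = "High"
    VERY_HIGH = "VeryHigh"


@dataclass(frozen=True)
class CoefficientSet:
    """The nine index weights C1-C9 (all strictly positive)."""

    c_A: float = 0.266
    c_WE: float = 0.227
    c_S: float = 0.056
    c_D: float = 0.064
    c_ON: float = 0.687
    c_LN: float = 0.660
    c_UPPE: float = 0.194
    c_NRR: float = 0.147
    c_APPE: float = 0.127

    def __post_init__(self) -> None:
        # positive weights make the index strictly increasing in every item;
        # non-positive weights are tolerated (e.g. sensitivity analyses) with
        # a warning rather than an error.
        bad = [f.name for f in fields(self) if getattr(self, f.name) <= 0]
        if bad:
            import warnings

            warnings.warn(
                f"non-positive weight(s) {bad}: OHLRA is no longer monotone "
                "in every item score",
                stacklevel=2,
            )

    def as_array(self):
        """Weights in item order (A, WE, S, D, ON, LN, UPPE, NRR, APPE)."""
        import numpy as np

        return np.array(
            [self.c_A, self.c_WE, self.c_S, self.c_D, self.c_ON,
             self.c_LN, self.c_UPPE, self.c_NRR, self.c_APPE]
        )


DEFAULT_COEFFICIENTS = CoefficientSet()


@dataclass(frozen=True)
class CutoffSet:
    """Three strictly increasing OHLRA thresholds separating the four risk levels.

    Optional per-threshold operating characteristics (sensitivity,
    specificity, AUC with 95% CI) may be attached when the cut-offs were
    derived from ROC curves.
    """

    t_low_mod: float
    t_mod_high: float
    t_high_vhigh: float
    sensitivity: tuple[float, float, float] | None = None
    specificity: tuple[float, float, float] | None = None
    auc: tuple[float, float, float] | None = None
    auc_ci: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.t_low_mod < self.t_mod_high < self.t_high_vhigh:
            raise ValueError("cut-offs must be strictly increasing")
        for name in ("sensitivity", "specificity"):
            vals = getattr(self, name)
            if vals is not None and not all(0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} values must lie in [0, 1]")


#: Published ROC cut-offs with their reported operating characteristics.
PAPER_CUTOFFS = CutoffSet(
    t_low_mod=4.85,
    t_mod_high=6.84,
    t_high_vhigh=7.59,
    sensitivity=(0.837, 0.921, 0.909),
    specificity=(0.840, 0.860, 0.879),
    auc=(0.922, 0.937, 0.952),
    auc_ci=((0.887, 0.957), (0.904, 0.970), (0.916, 0.988)),
)


@dataclass(frozen=True)
class OhlraAssessment:
    """A worker's OHLRA score and risk category, with the configuration used."""

    score: float
    category: RiskCategory
    cutoffs_used: CutoffSet
    coefficients_used: CoefficientSet


def compute_ohlra(items: ItemScoreVector, coeffs: CoefficientSet = DEFAULT_COEFFICIENTS) -> float:
    """Weighted sum of the nine item scores (D enters with its 0-5 count,
    ON/LN with their composite values)."""
    return (
        coeffs.c_A * items.A
        + coeffs.c_WE * items.WE
        + coeffs.c_S * items.S
        + coeffs.c_D * items.D
        + coeffs.c_ON * items.ON
        + coeffs.c_LN * items.LN
        + coeffs.c_UPPE * items.UPPE
        + coeffs.c_NRR * items.NRR
        + coeffs.c_APPE * items.APPE
    )


def categorize(score: float, cutoffs: CutoffSet = PAPER_CUTOFFS) -> RiskCategory:
    """Map a score to its risk level; boundary scores go to the higher category."""
    if not math.isfinite(score):
        raise ValueError(f"non-finite score: {score!r}")
    if score < cutoffs.t_low_mod:
        return RiskCategory.LOW
    if score < cutoffs.t_mod_high:
        return RiskCategory.MODERATE
    if score < cutoffs.t_high_vhigh:
        return RiskCategory.HIGH
    return RiskCategory.VERY_HIGH


def assess(
    items: ItemScoreVector,
    coeffs: CoefficientSet = DEFAULT_COEFFICIENTS,
    cutoffs: CutoffSet = PAPER_CUTOFFS,
) -> OhlraAssessment:
    """Score one worker and assign the risk category."""
    score = compute_ohlra(items, coeffs)
    return OhlraAssessment(score, categorize(score, cutoffs), cutoffs, coeffs)


# item-score extrema: ordinals 1..5, disease count 0..5, composites 0.2..5
_ITEM_MIN = (1, 1, 1, 0, 0.2, 0.2, 1, 1, 1)
_ITEM_MAX = (5, 5, 5, 5, 5.0, 5.0, 5, 5, 5)


def score_range(coeffs: CoefficientSet = DEFAULT_COEFFICIENTS) -> tuple[float, float]:
    """Attainable (min, max) OHLRA score under the item-score bounds."""
    w = (coeffs.c_A, coeffs.c_WE, coeffs.c_S, coeffs.c_D, coeffs.c_ON,
         coeffs.c_LN, coeffs.c_UPPE, coeffs.c_NRR, coeffs.c_APPE)
    lo = sum(wi * m for wi, m in zip(w, _ITEM_MIN))
    hi = sum(wi * m for wi, m in zip(w, _ITEM_MAX))
    return lo, hi
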