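"""Rubric scoring of worker attributes.

Each raw attribute (age, tenure, smoking, noise levels and durations, PPE
behaviour) is mapped onto a 1-5 Likert-type score by a fixed binning rubric;
the disease score is a 0-5 count of diagnosed conditions.  The two noise
exposures are then collapsed into composite scores::

    ON = tON * LON / 5        LN = tLN * LLN / 5

where ``tON``/``tLN`` score the daily exposure duration and ``LON``/``LLN``
score the noise level (occupational in dB(A); leisure as an ordinal
self-rating).  The composites live on the grid {t*l/5 : t,l in 1..5},
spanning 0.2 to 5.0.

Binning convention: bins are left-closed/right-open on the real line, except
that a rubric row printed as "more than U" makes the preceding bin closed at
U (e.g. occupational noise 86-90 dB scores 4 and anything strictly above
90 dB scores 5).  PPE awareness is reverse-coded (very low awareness scores
5).  The printed noise-reduction-rating rubric is non-monotone (two bins
score 4 and two score 5); by default the monotone-decreasing correction is
used (non-use 5, <5 dB 4, 5-10 3, 10-15 2, >15 1), with the printed mapping
available via ``nrr_rubric="as_printed"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "RawWorkerRecord",
    "ItemScoreVector",
    "DISEASES",
    "ITEM_NAMES",
    "NON_USE",
    "bin_score",
    "composite_noise_score",
    "disease_score",
    "score_record",
    "AGE_BINS",
    "WORK_EXPERIENCE_BINS",
    "SMOKING_BINS",
    "OCC_NOISE_LEVEL_BINS",
    "OCC_NOISE_TIME_BINS",
    "LEISURE_TIME_BINS",
    "NRR_BINS_CORRECTED",
    "NRR_BINS_AS_PRINTED",
]

#: Recognised diagnosed conditions, one point each.
DISEASES = frozenset(
    {"hypertension", "hyperlipidemia", "diabetes", "heart_disease", "head_or_ear_trauma"}
)

#: The nine index items, in index order.
ITEM_NAMES = ("A", "WE", "S", "D", "ON", "LN", "UPPE", "NRR", "APPE")

#: Sentinel accepted for ``ppe_nrr_dB`` when no hearing protector is worn.
NON_USE = "non-use"

# A bin is (upper_bound, score, upper_inclusive).  The final bin is unbounded.
# Upper bounds are the lower edge of the next printed label, except where the
# rubric ends in "more than U": there the previous bin closes at U.
Bin = tuple[float, int, bool]

AGE_BINS: list[Bin] = [(20, 1, False), (30, 2, False), (40, 3, False), (49, 4, True), (math.inf, 5, False)]
WORK_EXPERIENCE_BINS: list[Bin] = [(6, 1, False), (11, 2, False), (16, 3, False), (20, 4, True), (math.inf, 5, False)]
SMOKING_BINS: list[Bin] = [(1, 1, False), (6, 2, False), (10, 3, False), (20, 4, True), (math.inf, 5, False)]
OCC_NOISE_LEVEL_BINS: list[Bin] = [(75, 1, False), (81, 2, False), (86, 3, False), (90, 4, True), (math.inf, 5, False)]
OCC_NOISE_TIME_BINS: list[Bin] = [(2, 1, False), (4, 2, False), (6, 3, False), (8, 4, True), (math.inf, 5, False)]
LEISURE_TIME_BINS: list[Bin] = [(1, 1, False), (2, 2, False), (3, 3, False), (4, 4, True), (math.inf, 5, False)]
# Corrected, monotone-decreasing protection rubric (more attenuation = less risk).
NRR_BINS_CORRECTED: list[Bin] = [(5, 4, False), (10, 3, False), (15, 2, True), (math.inf, 1, False)]
# The rubric exactly as printed (non-monotone; kept for reproduction only).
NRR_BINS_AS_PRINTED: list[Bin] = [(5, 4, False), (10, 3, False), (15, 4, True), (math.inf, 5, False)]


@dataclass(frozen=True)
class RawWorkerRecord:
    """Raw attributes of one worker, plus an optional measured hearing loss.

    ``hearing_loss_dB`` is the worker's mean pure-tone threshold (dB HL);
    ``ppe_nrr_dB`` is the protector's noise reduction rating in dB, or the
    string sentinel ``"non-use"``.
    """

    age_years: int
    work_experience_years: int
    cigarettes_per_day: int
    diseases: frozenset[str]
    occ_noise_level_dBA: float
    occ_exposure_hours: float
    leisure_noise_level: int
    leisure_exposure_hours: float
    ppe_use_frequency: int
    ppe_nrr_dB: float | str
    ppe_awareness: int
    hearing_loss_dB: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.diseases) - DISEASES
        if unknown:
            raise ValueError(f"unknown disease condition(s): {sorted(unknown)}")
        for name in ("work_experience_years", "cigarettes_per_day", "occ_exposure_hours", "leisure_exposure_hours"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if isinstance(self.ppe_nrr_dB, str):
            if self.ppe_nrr_dB != NON_USE:
                raise ValueError(f"ppe_nrr_dB must be a number or {NON_USE!r}")
        elif self.ppe_nrr_dB < 0:
            raise ValueError("ppe_nrr_dB must be non-negative")
        for name in ("leisure_noise_level", "ppe_use_frequency", "ppe_awareness"):
            if not 1 <= getattr(self, name) <= 5:
                raise ValueError(f"{name} must be an ordinal in 1..5")
        if self.work_experience_years > self.age_years - 10:
            warnings.warn(
                f"work experience ({self.work_experience_years} y) exceeds "
                f"age - 10 ({self.age_years - 10} y); check the record",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ItemScoreVector:
    """The nine rubric item scores plus the four noise sub-scores."""

    A: int
    WE: int
    S: int
    D: int
    tON: int
    LON: int
    ON: float
    tLN: int
    LLN: int
    LN: float
    UPPE: int
    NRR: int
    APPE: int

    def __post_init__(self) -> None:
        for name in ("A", "WE", "S", "tON", "LON", "tLN", "LLN", "UPPE", "NRR", "APPE"):
            if not 1 <= getattr(self, name) <= 5:
                raise ValueError(f"{name} must lie in 1..5")
        if not 0 <= self.D <= 5:
            raise ValueError("D must lie in 0..5")
        if abs(self.ON - self.tON * self.LON / 5) > 1e-12:
            raise ValueError("ON must equal tON*LON/5")
        if abs(self.LN - self.tLN * self.LLN / 5) > 1e-12:
            raise ValueError("LN must equal tLN*LLN/5")

    def as_dict(self) -> dict[str, float]:
        """Item scores keyed by symbol, in index order (sub-scores included)."""
        return {
            "A": self.A, "WE": self.WE, "S": self.S, "D": self.D,
            "tON": self.tON, "LON": self.LON, "ON": self.ON,
            "tLN": self.tLN, "LLN": self.LLN, "LN": self.LN,
            "UPPE": self.UPPE, "NRR": self.NRR, "APPE": self.APPE,
        }


def bin_score(value: float, bins: Iterable[Bin]) -> int:
    """Score ``value`` against an ordered rubric bin list.

    Returns the score of the first bin containing ``value``; bins are
    left-closed/right-open except where flagged upper-inclusive.  The final
    bin must be unbounded (upper bound ``inf``).
    """
    bins = list(bins)
    if not bins:
        raise ValueError("empty bin list")
    if not math.isfinite(value):
        raise ValueError(f"non-finite value: {value!r}")
    for upper, score, inclusive in bins:
        if value < upper or (inclusive and value == upper):
            return score
    return bins[-1][1]


def composite_noise_score(t_score: int, level_score: int) -> float:
    """Composite exposure score ``t*level/5`` for duration and level scores in 1..5."""
    for name, v in (("t_score", t_score), ("level_score", level_score)):
        if v not in (1, 2, 3, 4, 5):
            raise ValueError(f"{name} must be an integer in 1..5, got {v!r}")
    return t_score * level_score / 5


def disease_score(diseases: Iterable[str]) -> int:
    """One point per diagnosed condition, 0-5."""
    ds = set(diseases)
    unknown = ds - DISEASES
    if unknown:
        raise ValueError(f"unknown disease condition(s): {sorted(unknown)}")
    return len(ds)


def _nrr_score(nrr: float | str, bins: list[Bin]) -> int:
    if isinstance(nrr, str) or nrr is None:
        return 5  # non-use
    return bin_score(float(nrr), bins)


def score_record(
    record: RawWorkerRecord,
    *,
    nrr_rubric: str = "corrected",
    reverse_ppe_use: bool = False,
) -> ItemScoreVector:
    """Apply every rubric to one worker record.

    Pure function: the same record always yields the same vector.
    ``reverse_ppe_use`` recodes PPE use frequency as 6 - frequency for
    sensitivity analyses (the default keeps the rubric as printed, where
    "always" scores 5).
    """
    if nrr_rubric not in ("corrected", "as_printed"):
        raise ValueError("nrr_rubric must be 'corrected' or 'as_printed'")
    nrr_bins = NRR_BINS_CORRECTED if nrr_rubric == "corrected" else NRR_BINS_AS_PRINTED

    def _score(field_name: str, value: float, bins: list[Bin]) -> int:
        try:
            return bin_score(value, bins)
        except ValueError as exc:
            raise ValueError(f"field {field_name!r}: {exc}") from exc

    tON = _score("occ_exposure_hours", record.occ_exposure_hours, OCC_NOISE_TIME_BINS)
    LON = _score("occ_noise_level_dBA", record.occ_noise_level_dBA, OCC_NOISE_LEVEL_BINS)
    tLN = _score("leisure_exposure_hours", record.leisure_exposure_hours, LEISURE_TIME_BINS)
    LLN = record.leisure_noise_level
    uppe = record.ppe_use_frequency
    if reverse_ppe_use:
        uppe = 6 - uppe
    return ItemScoreVector(
        A=_score("age_years", record.age_years, AGE_BINS),
        WE=_score("work_experience_years", record.work_experience_years, WORK_EXPERIENCE_BINS),
        S=_score("cigarettes_per_day", record.cigarettes_per_day, SMOKING_BINS),
        D=disease_score(record.diseases),
        tON=tON,
        LON=LON,
        ON=composite_noise_score(tON, LON),
        tLN=tLN,
        LLN=LLN,
        LN=composite_noise_score(tLN, LLN),
        UPPE=uppe,
        NRR=_nrr_score(record.ppe_nrr_dB, nrr_bins),
        APPE=6 - record.ppe_awareness,  # awareness is reverse-coded
    )
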