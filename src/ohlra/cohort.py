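"""Calibrated synthetic cohorts of noise-exposed workers.

The study cohort (n = 220 steel-factory workers) is not deposited, so every
pipeline stage is exercised on synthetic cohorts that reproduce its published
summary statistics: the item-score means and standard deviations and the
10x10 Pearson correlation matrix of the nine rubric items with hearing loss.

The dependence model is a Gaussian copula: a latent multivariate normal with
the target correlation matrix, transformed marginal-by-marginal.  In
*continuous* mode each variable is an affine transform of its latent normal
(hearing loss clamped at 0 dB HL); this is the minimal faithful model given
that only Pearson correlations and approximate normality were reported.  In
*discrete* mode each item score is additionally ordinalized onto its
rubric-legal grid by thresholding the latent normal, with the thresholds
shifted so the discretized mean matches the target mean (moment-matched
ordinalization; correlations attenuate slightly, which is documented rather
than corrected).

``generate_raw_records`` inverts the scoring rubric: it draws discrete item
scores, then samples a raw attribute uniformly inside the score's bin, so
re-scoring the record reproduces the item scores exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from statsmodels.stats.correlation_tools import corr_nearest

from .rubric import DISEASES

__all__ = [
    "CohortMoments",
    "VARIABLE_NAMES",
    "default_moments",
    "nearest_correlation",
    "generate_cohort",
    "generate_raw_records",
    "DEFAULT_SEED",
]

#: Column order: nine item scores then hearing loss (dB HL).
VARIABLE_NAMES = ("A", "WE", "S", "D", "ON", "LN", "UPPE", "NRR", "APPE", "hearing_loss")

#: Default fixture seed (publication date of the calibration tables).
DEFAULT_SEED = 20241117

_MEANS = (3.10, 2.80, 1.68, 0.71, 2.28, 1.80, 2.91, 2.91, 2.18, 31.46)
_SDS = (0.82, 1.22, 0.74, 0.72, 0.95, 1.33, 1.36, 1.19, 0.81, 17.95)
# Lower triangle of the published Pearson correlation matrix.
_CORR_LOWER = (
    (1.000,),
    (0.778, 1.000),
    (0.286, 0.230, 1.000),
    (0.208, 0.169, 0.365, 1.000),
    (0.454, 0.438, 0.203, 0.238, 1.000),
    (0.330, 0.337, 0.107, 0.147, 0.740, 1.000),
    (0.129, 0.085, 0.179, 0.094, 0.201, 0.260, 1.000),
    (0.202, 0.176, 0.039, 0.220, 0.336, 0.378, 0.196, 1.000),
    (0.186, 0.158, 0.169, 0.196, 0.280, 0.265, 0.350, 0.258, 1.000),
    (0.481, 0.456, 0.172, 0.282, 0.791, 0.709, 0.374, 0.413, 0.327, 1.000),
)

# Rubric-legal score grids used for moment-matched ordinalization.  The two
# composite exposures live on the attainable products {t*l/5}.
_COMPOSITE_GRID = tuple(sorted({t * l / 5 for t in range(1, 6) for l in range(1, 6)}))
ITEM_GRIDS: dict[str, tuple[float, ...]] = {
    "A": (1, 2, 3, 4, 5),
    "WE": (1, 2, 3, 4, 5),
    "S": (1, 2, 3, 4, 5),
    "D": (0, 1, 2, 3, 4, 5),
    "ON": _COMPOSITE_GRID,
    "LN": _COMPOSITE_GRID,
    "UPPE": (1, 2, 3, 4, 5),
    "NRR": (1, 2, 3, 4, 5),
    "APPE": (1, 2, 3, 4, 5),
}


@dataclass(frozen=True)
class CohortMoments:
    """Means, SDs and correlation matrix of the nine items plus hearing loss."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray
    n_reference: int = 220

    def __post_init__(self) -> None:
        p = len(self.names)
        if self.means.shape != (p,) or self.sds.shape != (p,) or self.corr.shape != (p, p):
            raise ValueError("inconsistent moment dimensions")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(self.sds <= 0):
            raise ValueError("standard deviations must be positive")

    @property
    def is_psd(self) -> bool:
        return float(np.linalg.eigvalsh(self.corr).min()) >= -1e-10

    def covariance(self) -> np.ndarray:
        return self.corr * np.outer(self.sds, self.sds)

    def repaired(self) -> "CohortMoments":
        """Moments with the correlation matrix projected to the nearest PSD one."""
        fixed, _ = nearest_correlation(self.corr)
        return replace(self, corr=fixed)


def default_moments() -> CohortMoments:
    """The packaged calibration constants (study summary statistics, n = 220)."""
    p = len(VARIABLE_NAMES)
    corr = np.zeros((p, p))
    for i, row in enumerate(_CORR_LOWER):
        for j, v in enumerate(row):
            corr[i, j] = corr[j, i] = v
    return CohortMoments(
        names=VARIABLE_NAMES,
        means=np.array(_MEANS),
        sds=np.array(_SDS),
        corr=corr,
    )


def nearest_correlation(matrix: np.ndarray, threshold: float = 1e-12) -> tuple[np.ndarray, float]:
    """Nearest (Frobenius) PSD correlation matrix, by alternating projections.

    Returns ``(repaired, frobenius_distance)``; an already-PSD input is
    returned unchanged with distance 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T):
        raise ValueError("input must be symmetric")
    if float(np.linalg.eigvalsh(matrix).min()) >= -1e-12:
        return matrix, 0.0
    fixed = corr_nearest(matrix, threshold=threshold, n_fact=1000)
    return fixed, float(np.linalg.norm(fixed - matrix, "fro"))


def _ordinalize(z: np.ndarray, grid: tuple[float, ...], mean: float, sd: float) -> np.ndarray:
    """Map standard-normal draws onto ``grid`` so the sample mean matches ``mean``.

    Thresholds start at the midpoints of the grid under the target normal
    marginal and are then shifted by a common offset solved so the *expected*
    discretized mean equals the target (monotone in the offset).
    """
    grid_arr = np.asarray(grid, dtype=float)
    mids = (grid_arr[:-1] + grid_arr[1:]) / 2
    base = (mids - mean) / sd  # z-scale thresholds

    def expected_mean(delta: float) -> float:
        cdf = norm.cdf(base + delta)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(probs @ grid_arr)

    lo, hi = -4.0, 4.0
    if (expected_mean(lo) - mean) * (expected_mean(hi) - mean) > 0:
        delta = 0.0  # target mean unreachable on this grid; keep midpoints
    else:
        delta = brentq(lambda d: expected_mean(d) - mean, lo, hi, xtol=1e-10)
    thresholds = base + delta
    return grid_arr[np.searchsorted(thresholds, z)]


def generate_cohort(
    moments: CohortMoments | None = None,
    n: int = 220,
    seed: int = DEFAULT_SEED,
    mode: str = "continuous",
    clamp_hearing_loss_range: bool = False,
    clamp_hearing_loss_at_zero: bool = True,
) -> pd.DataFrame:
    """Draw a synthetic cohort with the target correlation structure.

    continuous mode: each variable is ``z*sd + mean`` (hearing loss clamped
    at >= 0 dB HL by default; disable ``clamp_hearing_loss_at_zero`` when an
    exactly Gaussian outcome is needed, e.g. to cross-check closed-form
    moment identities).  discrete mode: item scores are moment-matched onto
    their rubric grids; hearing loss stays continuous.  Fully reproducible
    for a given (moments, n, seed, mode).
    """
    if moments is None:
        moments = default_moments()
    if mode not in ("continuous", "discrete"):
        raise ValueError("mode must be 'continuous' or 'discrete'")
    if n < 10:
        raise ValueError("n must be at least 10")
    if not moments.is_psd:
        raise ValueError(
            "correlation matrix is not positive semi-definite; repair it "
            "first with nearest_correlation / CohortMoments.repaired()"
        )
    rng = np.random.default_rng(seed)
    # Cholesky with a tiny ridge in case of a semidefinite (repaired) matrix
    corr = moments.corr + 1e-12 * np.eye(len(moments.names))
    z = rng.standard_normal((n, len(moments.names))) @ np.linalg.cholesky(corr).T

    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(moments.names):
        if name == "hearing_loss" or mode == "continuous":
            col = z[:, j] * moments.sds[j] + moments.means[j]
            if name == "hearing_loss":
                if clamp_hearing_loss_at_zero:
                    col = np.clip(col, 0.0, None)
                if clamp_hearing_loss_range:
                    col = np.clip(col, 10.0, 67.26)
        else:
            col = _ordinalize(z[:, j], ITEM_GRIDS[name], moments.means[j], moments.sds[j])
        data[name] = col
    return pd.DataFrame(data)


# Raw-value ranges per score bin, matched to the scoring rubric.  Integer
# bins sample uniform integers; real bins sample uniform reals in [lo, hi)
# chosen strictly inside the bin so re-scoring is exact.
_AGE_RANGES = {1: (18, 19), 2: (20, 29), 3: (30, 39), 4: (40, 49), 5: (50, 60)}
_WE_RANGES = {1: (1, 5), 2: (6, 10), 3: (11, 15), 4: (16, 20), 5: (21, 30)}
_SMOKE_RANGES = {1: (0, 0), 2: (1, 5), 3: (6, 9), 4: (10, 20), 5: (21, 40)}
_OCC_DB_RANGES = {1: (65.0, 75.0), 2: (75.0, 81.0), 3: (81.0, 86.0), 4: (86.0, 90.0), 5: (90.5, 100.0)}
_OCC_HOURS_RANGES = {1: (0.5, 2.0), 2: (2.0, 4.0), 3: (4.0, 6.0), 4: (6.0, 8.0), 5: (8.5, 12.0)}
_LEIS_HOURS_RANGES = {1: (0.0, 1.0), 2: (1.0, 2.0), 3: (2.0, 3.0), 4: (3.0, 4.0), 5: (4.5, 8.0)}
_NRR_RANGES = {4: (0.0, 5.0), 3: (5.0, 10.0), 2: (10.0, 15.0), 1: (15.5, 30.0)}

# factor pairs (t, l) realizing each composite grid value
_COMPOSITE_FACTORS: dict[float, list[tuple[int, int]]] = {}
for _t in range(1, 6):
    for _l in range(1, 6):
        _COMPOSITE_FACTORS.setdefault(_t * _l / 5, []).append((_t, _l))


def _uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _uniform_real(rng: np.random.Generator, lo: float, hi: float, decimals: int) -> float:
    # floor (not round) so the reported value cannot cross the bin's upper edge
    scale = 10**decimals
    return float(np.floor(rng.uniform(lo, hi) * scale) / scale)


def generate_raw_records(
    n: int,
    seed: int = DEFAULT_SEED,
    moments: CohortMoments | None = None,
) -> pd.DataFrame:
    """Raw worker records whose rubric scores reproduce a discrete cohort draw.

    Each discrete item score is inverted by sampling a raw value uniformly
    inside its rubric bin; composite exposures pick a (duration, level)
    factor pair uniformly among those realizing the composite value.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    scores = generate_cohort(moments, n=max(n, 10), seed=seed, mode="discrete").iloc[:n]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    disease_list = sorted(DISEASES)

    rows = []
    for _, s in scores.iterrows():
        t_on, l_on = _COMPOSITE_FACTORS[float(s["ON"])][
            rng.integers(len(_COMPOSITE_FACTORS[float(s["ON"])]))
        ]
        t_ln, l_ln = _COMPOSITE_FACTORS[float(s["LN"])][
            rng.integers(len(_COMPOSITE_FACTORS[float(s["LN"])]))
        ]
        nrr_score = int(s["NRR"])
        if nrr_score == 5:
            nrr: float | str = "non-use"
        else:
            nrr = _uniform_real(rng, *_NRR_RANGES[nrr_score], decimals=1)
        diseases = ";".join(rng.choice(disease_list, size=int(s["D"]), replace=False))
        rows.append(
            {
                "age_years": _uniform_int(rng, *_AGE_RANGES[int(s["A"])]),
                "work_experience_years": _uniform_int(rng, *_WE_RANGES[int(s["WE"])]),
                "cigarettes_per_day": _uniform_int(rng, *_SMOKE_RANGES[int(s["S"])]),
                "diseases": diseases,
                "occ_noise_level_dBA": _uniform_real(rng, *_OCC_DB_RANGES[l_on], decimals=1),
                "occ_exposure_hours": _uniform_real(rng, *_OCC_HOURS_RANGES[t_on], decimals=2),
                "leisure_noise_level": l_ln,
                "leisure_exposure_hours": _uniform_real(rng, *_LEIS_HOURS_RANGES[t_ln], decimals=2),
                "ppe_use_frequency": int(s["UPPE"]),
                "ppe_nrr_dB": nrr,
                "ppe_awareness": 6 - int(s["APPE"]),
                "hearing_loss_dB": round(float(s["hearing_loss"]), 2),
            }
        )
    return pd.DataFrame(rows)
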