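"""Three-factor covariance-structure (path) model for hearing loss.

Nine observed item scores load on three correlated latent factors —
personal attributes (A, WE, S, D), noise exposure (ON, LN) and hearing
protection (UPPE, NRR, APPE) — and each factor has a direct structural path
to observed hearing loss:

    x_i = lambda_i * eta_f(i) + eps_i          (measurement model)
    y   = b_personal*eta_1 + b_noise*eta_2 + b_ppe*eta_3 + zeta

Latent variances are fixed at 1 for identification (so all nine loadings are
free) and latent correlations are free.  Estimation is maximum likelihood on
the sample covariance matrix: the fit function

    F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p

is minimized by quasi-Newton iteration.  In the standardized solution the
loadings are the per-item "direct" effects, the structural coefficients are
the per-factor "total" effects, and each item's indirect effect on hearing
loss is the product loading x factor path.  The published solution has
loadings 0.980/0.837/0.207/0.236 (personal), 0.994/0.955 (noise) and
0.429/0.325/0.280 (protection) with factor paths 0.271, 0.691 and 0.452.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import approx_fprime, minimize

from .cohort import nearest_correlation

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "FitIndices",
    "DEFAULT_SPEC",
    "REFERENCE_EFFECTS",
    "ml_discrepancy",
    "fit_path_model",
    "indirect_effects",
    "fit_indices",
    "implied_covariance",
]

_GRAD_TOL = 1e-6
_RESID_FLOOR = 1e-6  # Heywood clamp


@dataclass(frozen=True)
class PathModelSpec:
    """Factor membership of the nine items and the observed outcome."""

    factor_membership: dict[str, list[str]] = field(
        default_factory=lambda: {
            "personal": ["A", "WE", "S", "D"],
            "noise": ["ON", "LN"],
            "ppe": ["UPPE", "NRR", "APPE"],
        }
    )
    outcome: str = "hearing_loss"

    def __post_init__(self) -> None:
        items = [i for members in self.factor_membership.values() for i in members]
        if len(items) != len(set(items)):
            raise ValueError("each item must belong to exactly one factor")

    @property
    def items(self) -> list[str]:
        return [i for members in self.factor_membership.values() for i in members]

    @property
    def factors(self) -> list[str]:
        return list(self.factor_membership)

    def factor_of(self, item: str) -> str:
        for f, members in self.factor_membership.items():
            if item in members:
                return f
        raise KeyError(item)


DEFAULT_SPEC = PathModelSpec()

#: Published standardized solution (per-item loadings and per-factor paths).
REFERENCE_EFFECTS = {
    "loadings": {
        "A": 0.980, "WE": 0.837, "S": 0.207, "D": 0.236,
        "ON": 0.994, "LN": 0.955,
        "UPPE": 0.429, "NRR": 0.325, "APPE": 0.280,
    },
    "paths": {"personal": 0.271, "noise": 0.691, "ppe": 0.452},
    "indirect": {
        "A": 0.266, "WE": 0.227, "S": 0.056, "D": 0.064,
        "ON": 0.687, "LN": 0.660,
        "UPPE": 0.194, "NRR": 0.147, "APPE": 0.127,
    },
}


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    chi2_over_df: float
    rmsea: float
    gfi: float
    agfi: float
    nfi: float
    cfi: float
    ifi: float


@dataclass(frozen=True)
class PathModelFit:
    """Standardized solution of the three-factor model."""

    loadings: dict[str, float]
    paths: dict[str, float]
    indirect: dict[str, float]
    latent_cov: np.ndarray
    fit: FitIndices
    n: int
    converged: bool
    spec: PathModelSpec = DEFAULT_SPEC

    def __post_init__(self) -> None:
        for item, load in self.loadings.items():
            if abs(load) > 1.05:
                warnings.warn(
                    f"standardized loading of {item} is {load:.3f} (>1.05): "
                    "possible Heywood case",
                    stacklevel=2,
                )


def ml_discrepancy(sample_cov: np.ndarray, model_cov: np.ndarray) -> float:
    """ML fit function log|Sigma| + tr(S Sigma^-1) - log|S| - p (0 iff S == Sigma)."""
    S = np.asarray(sample_cov, dtype=float)
    Sigma = np.asarray(model_cov, dtype=float)
    if S.shape != Sigma.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("sample covariance must be symmetric positive definite")
    if sign_m <= 0 or np.linalg.eigvalsh(Sigma).min() <= 0:
        raise ValueError("model covariance must be symmetric positive definite")
    return float(logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def _unpack(theta: np.ndarray, n_items: int, n_factors: int):
    k = n_items
    q = n_factors
    lam = theta[:k]
    b = theta[k : k + q]
    rho = theta[k + q : k + q + q * (q - 1) // 2]
    resid = theta[k + q + q * (q - 1) // 2 : k + q + q * (q - 1) // 2 + k]
    resid_y = theta[-1]
    psi = np.eye(q)
    idx = 0
    for i in range(q):
        for j in range(i):
            psi[i, j] = psi[j, i] = rho[idx]
            idx += 1
    return lam, b, psi, resid, resid_y


def implied_covariance(
    lam: np.ndarray, b: np.ndarray, psi: np.ndarray, resid: np.ndarray,
    resid_y: float, factor_index: np.ndarray,
) -> np.ndarray:
    """Model-implied covariance of (items..., outcome)."""
    k = len(lam)
    L = np.zeros((k, len(b)))
    L[np.arange(k), factor_index] = lam
    cov_xx = L @ psi @ L.T + np.diag(resid)
    cov_xy = L @ psi @ b
    var_y = float(b @ psi @ b) + resid_y
    top = np.column_stack([cov_xx, cov_xy])
    bottom = np.concatenate([cov_xy, [var_y]])
    return np.vstack([top, bottom])


def fit_path_model(
    sample_cov: np.ndarray,
    n: int,
    spec: PathModelSpec = DEFAULT_SPEC,
    names: tuple[str, ...] | None = None,
) -> PathModelFit:
    """Fit the three-factor model to a (p x p) covariance by maximum likelihood.

    ``names`` gives the row order of ``sample_cov``; defaults to the spec's
    items followed by the outcome.  A non-PSD input is repaired (nearest PSD
    correlation on the correlation scale) with a warning; non-convergence is
    reported via the ``converged`` flag, never raised.
    """
    items = spec.items
    factors = spec.factors
    if names is None:
        names = tuple(items) + (spec.outcome,)
    order = [list(names).index(v) for v in items + [spec.outcome]]
    S = np.asarray(sample_cov, dtype=float)[np.ix_(order, order)]
    p = len(order)
    if n <= 30:
        raise ValueError("n must exceed 30")

    if np.linalg.eigvalsh(S).min() <= 0:
        warnings.warn("sample covariance not positive definite; repairing", stacklevel=2)
        d = np.sqrt(np.diag(S))
        corr, _ = nearest_correlation(S / np.outer(d, d))
        corr = corr + 1e-8 * np.eye(p)
        S = corr * np.outer(d, d)

    # standardize: fit the correlation matrix so the solution is standardized
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)

    k, q = len(items), len(factors)
    factor_index = np.array([factors.index(spec.factor_of(i)) for i in items])

    def sigma_of(theta: np.ndarray) -> np.ndarray:
        lam, b, psi, resid, resid_y = _unpack(theta, k, q)
        return implied_covariance(lam, b, psi, np.maximum(resid, _RESID_FLOOR),
                                  max(resid_y, _RESID_FLOOR), factor_index)

    def objective(theta: np.ndarray) -> float:
        Sigma = sigma_of(theta)
        ev = np.linalg.eigvalsh(Sigma)
        if ev.min() <= 1e-10:
            return 1e6 - 1e4 * ev.min()
        sign, logdet = np.linalg.slogdet(Sigma)
        return float(logdet + np.trace(np.linalg.solve(Sigma, R)))

    n_rho = q * (q - 1) // 2
    theta0 = np.concatenate([
        np.full(k, 0.7),          # loadings
        np.full(q, 0.3),          # structural paths
        np.full(n_rho, 0.3),      # latent correlations
        np.full(k, 0.5),          # item residuals (0.5 * diag of R)
        [0.5],                    # outcome residual
    ])
    bounds = (
        [(-2.0, 2.0)] * k
        + [(-2.0, 2.0)] * q
        + [(-0.95, 0.95)] * n_rho
        + [(_RESID_FLOOR, 4.0)] * (k + 1)
    )
    res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    theta = res.x
    grad_norm = float(np.linalg.norm(approx_fprime(theta, objective, 1e-7)))
    converged = bool(res.success) and grad_norm < max(_GRAD_TOL, 1e-4)

    lam, b, psi, resid, resid_y = _unpack(theta, k, q)
    resid = np.maximum(resid, _RESID_FLOOR)
    resid_y = max(resid_y, _RESID_FLOOR)
    Sigma = sigma_of(theta)

    # standardize against the implied variances (diag(Sigma) ~ 1 already)
    sd_impl = np.sqrt(np.diag(Sigma))
    lam_std = lam / sd_impl[:k]
    b_std = b / sd_impl[k]
    # sign convention: factors oriented so their path to the outcome is >= 0
    for f in range(q):
        if b_std[f] < 0:
            b_std[f] = -b_std[f]
            lam_std[factor_index == f] *= -1
            psi[f, :] *= -1
            psi[:, f] *= -1
            psi[f, f] = 1.0

    loadings = {item: float(lam_std[i]) for i, item in enumerate(items)}
    paths = {f: float(b_std[j]) for j, f in enumerate(factors)}
    indirect = indirect_effects(loadings, paths, spec)

    chi2 = (n - 1) * max(ml_discrepancy(R, Sigma), 0.0)
    n_params = k + q + n_rho + k + 1
    df = p * (p + 1) // 2 - n_params
    null_cov = np.eye(p)  # independence model on the correlation scale
    chi2_null = (n - 1) * ml_discrepancy(R, null_cov)
    df_null = p * (p - 1) // 2
    fit = fit_indices(chi2, df, chi2_null, df_null, n, R, Sigma)

    return PathModelFit(
        loadings=loadings, paths=paths, indirect=indirect,
        latent_cov=psi, fit=fit, n=n, converged=converged, spec=spec,
    )


def indirect_effects(
    loadings: dict[str, float],
    paths: dict[str, float],
    spec: PathModelSpec = DEFAULT_SPEC,
) -> dict[str, float]:
    """Per-item indirect effect on the outcome: loading x factor path."""
    out = {}
    for item, load in loadings.items():
        factor = spec.factor_of(item)
        if factor not in paths:
            raise KeyError(f"no structural path for factor {factor!r}")
        out[item] = load * paths[factor]
    return out


def fit_indices(
    chi2: float,
    df: int,
    chi2_null: float,
    df_null: int,
    n: int,
    sample_cov: np.ndarray,
    model_cov: np.ndarray,
) -> FitIndices:
    """Absolute, comparative and normed fit indices for a fitted model.

    The null model is the independence (diagonal covariance) model with
    df_null = p(p-1)/2.
    """
    if df < 0 or n <= 1:
        raise ValueError("df must be >= 0 and n > 1")
    S = np.asarray(sample_cov, dtype=float)
    Sigma = np.asarray(model_cov, dtype=float)
    if df == 0:
        if chi2 > 1e-10:
            warnings.warn("df = 0 with chi2 > 0: RMSEA undefined, reported as 0", stacklevel=2)
        rmsea = 0.0
        chi2_over_df = 0.0
        agfi = 1.0
    else:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        chi2_over_df = chi2 / df
    W = np.linalg.solve(Sigma, S)
    p = S.shape[0]
    gfi = float(1 - np.trace((W - np.eye(p)) @ (W - np.eye(p))) / np.trace(W @ W))
    if df > 0:
        agfi = float(1 - (p * (p + 1) / (2 * df)) * (1 - gfi))
    nfi = float((chi2_null - chi2) / chi2_null) if chi2_null > 0 else 1.0
    denom = max(chi2_null - df_null, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else float(1 - max(chi2 - df, 0.0) / denom)
    ifi = float((chi2_null - chi2) / (chi2_null - df)) if chi2_null != df else 1.0
    return FitIndices(
        chi2=float(chi2), df=int(df), chi2_over_df=float(chi2_over_df),
        rmsea=rmsea, gfi=gfi, agfi=agfi, nfi=nfi,
        cfi=float(min(max(cfi, 0.0), 1.0)), ifi=ifi,
    )
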