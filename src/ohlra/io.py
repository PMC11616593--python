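"""Cohort file I/O and table-level scoring.

Two CSV dialects are accepted: *raw* (one worker per row, attribute columns
matching :class:`~ohlra.rubric.RawWorkerRecord`, diseases as
semicolon-separated tokens, ``non-use`` sentinel for the NRR) and *scored*
(pre-computed item scores A..APPE).  Missing raw fields are a hard error —
no imputation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .index import CoefficientSet, CutoffSet, DEFAULT_COEFFICIENTS, PAPER_CUTOFFS, categorize, compute_ohlra
from .rubric import NON_USE, RawWorkerRecord, score_record

__all__ = [
    "RAW_COLUMNS",
    "SCORED_COLUMNS",
    "read_cohort",
    "record_from_row",
    "score_cohort",
    "assess_cohort",
    "load_config",
    "default_config",
    "config_hash",
]

RAW_COLUMNS = (
    "age_years", "work_experience_years", "cigarettes_per_day", "diseases",
    "occ_noise_level_dBA", "occ_exposure_hours", "leisure_noise_level",
    "leisure_exposure_hours", "ppe_use_frequency", "ppe_nrr_dB",
    "ppe_awareness",
)
SCORED_COLUMNS = ("A", "WE", "S", "D", "tON", "LON", "tLN", "LLN", "UPPE", "NRR", "APPE")
_OPTIONAL = ("hearing_loss_dB",)

_INT_RAW = ("age_years", "work_experience_years", "cigarettes_per_day",
            "leisure_noise_level", "ppe_use_frequency", "ppe_awareness")
_FLOAT_RAW = ("occ_noise_level_dBA", "occ_exposure_hours", "leisure_exposure_hours")


def detect_dialect(columns) -> str:
    cols = set(columns)
    if set(RAW_COLUMNS) <= cols:
        return "raw"
    if set(SCORED_COLUMNS) <= cols:
        return "scored"
    raise ValueError(
        "header matches neither the raw nor the scored cohort dialect; "
        f"got columns {sorted(cols)}"
    )


def read_cohort(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read and validate a cohort CSV; returns a typed DataFrame.

    Row-level problems are collected and reported together with their row
    numbers (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"diseases": str, "ppe_nrr_dB": str})
    if df.empty:
        raise ValueError(f"{path}: empty cohort file")
    found = detect_dialect(df.columns)
    if dialect not in ("auto", found):
        raise ValueError(f"{path}: expected {dialect} dialect, found {found}")

    errors: list[str] = []
    if found == "raw":
        df["diseases"] = df["diseases"].fillna("")
        for col in _INT_RAW:
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError):
                errors.append(f"column {col!r}: non-integer values")
        for col in _FLOAT_RAW + _OPTIONAL:
            if col in df.columns:
                try:
                    df[col] = df[col].astype(float)
                except (ValueError, TypeError):
                    errors.append(f"column {col!r}: unparseable values")

        def _nrr(v):
            if isinstance(v, str) and v.strip() == NON_USE:
                return NON_USE
            try:
                return float(v)
            except (ValueError, TypeError):
                return None

        parsed = df["ppe_nrr_dB"].map(_nrr)
        for row in df.index[[p is None for p in parsed]]:
            errors.append(f"row {row + 1}: unparseable ppe_nrr_dB {df.at[row, 'ppe_nrr_dB']!r}")
        df["ppe_nrr_dB"] = parsed
        required = [c for c in RAW_COLUMNS]
    else:
        for col in SCORED_COLUMNS:
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError):
                errors.append(f"column {col!r}: non-integer values")
        if "hearing_loss_dB" in df.columns:
            df["hearing_loss_dB"] = df["hearing_loss_dB"].astype(float)
        required = list(SCORED_COLUMNS)

    for row in df.index[df[required].isna().any(axis=1)]:
        missing = [c for c in required if pd.isna(df.at[row, c])]
        errors.append(f"row {row + 1}: missing value(s) in {missing}")
    if errors:
        raise ValueError(f"{path}: invalid cohort file:\n  " + "\n  ".join(errors[:20]))
    df.attrs["dialect"] = found
    return df


def record_from_row(row: pd.Series) -> RawWorkerRecord:
    """Build a validated worker record from one raw-dialect table row."""
    diseases = frozenset(t.strip() for t in str(row["diseases"]).split(";") if t.strip())
    hl = row.get("hearing_loss_dB")
    return RawWorkerRecord(
        age_years=int(row["age_years"]),
        work_experience_years=int(row["work_experience_years"]),
        cigarettes_per_day=int(row["cigarettes_per_day"]),
        diseases=diseases,
        occ_noise_level_dBA=float(row["occ_noise_level_dBA"]),
        occ_exposure_hours=float(row["occ_exposure_hours"]),
        leisure_noise_level=int(row["leisure_noise_level"]),
        leisure_exposure_hours=float(row["leisure_exposure_hours"]),
        ppe_use_frequency=int(row["ppe_use_frequency"]),
        ppe_nrr_dB=row["ppe_nrr_dB"],
        ppe_awareness=int(row["ppe_awareness"]),
        hearing_loss_dB=None if hl is None or pd.isna(hl) else float(hl),
    )


def score_cohort(
    df: pd.DataFrame,
    *,
    nrr_rubric: str = "corrected",
    reverse_ppe_use: bool = False,
) -> pd.DataFrame:
    """Item scores for a raw-dialect cohort table (scored tables pass through).

    The output carries the full score columns (incl. tON/LON/tLN/LLN and the
    ON/LN composites) plus ``hearing_loss_dB`` when present.
    """
    if df.attrs.get("dialect") == "scored" or set(SCORED_COLUMNS) <= set(df.columns):
        out = df.copy()
        if "ON" not in out.columns:
            out["ON"] = out["tON"] * out["LON"] / 5
            out["LN"] = out["tLN"] * out["LLN"] / 5
        return out
    rows = []
    for idx, row in df.iterrows():
        try:
            rec = record_from_row(row)
            vec = score_record(rec, nrr_rubric=nrr_rubric, reverse_ppe_use=reverse_ppe_use)
        except ValueError as exc:
            raise ValueError(f"row {idx + 1}: {exc}") from exc
        d = vec.as_dict()
        if rec.hearing_loss_dB is not None:
            d["hearing_loss_dB"] = rec.hearing_loss_dB
        rows.append(d)
    return pd.DataFrame(rows)


def assess_cohort(
    scored: pd.DataFrame,
    coeffs: CoefficientSet = DEFAULT_COEFFICIENTS,
    cutoffs: CutoffSet = PAPER_CUTOFFS,
) -> pd.DataFrame:
    """Append ``ohlra_score`` and ``risk_category`` columns to a scored table."""
    w = coeffs.as_array()
    items = scored[["A", "WE", "S", "D", "ON", "LN", "UPPE", "NRR", "APPE"]].to_numpy(dtype=float)
    out = scored.copy()
    out["ohlra_score"] = items @ w
    out["risk_category"] = [categorize(s, cutoffs).value for s in out["ohlra_score"]]
    return out


def default_config() -> dict:
    """Configuration reproducing the published constants."""
    return {
        "coefficients": {k.replace("c_", ""): v for k, v in vars(DEFAULT_COEFFICIENTS).items()},
        "cutoffs": {
            "low_moderate": PAPER_CUTOFFS.t_low_mod,
            "moderate_high": PAPER_CUTOFFS.t_mod_high,
            "high_very_high": PAPER_CUTOFFS.t_high_vhigh,
        },
        "rubric": {"nrr_rubric": "corrected", "reverse_ppe_use": False},
        "hl_thresholds": [25.0, 40.0, 60.0],
        "simulate": {"n": 220, "seed": 1, "mode": "discrete"},
        "fit_sem": True,
    }


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, filling unspecified sections from the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def coefficients_from_config(cfg: dict) -> CoefficientSet:
    c = cfg.get("coefficients", {})
    return CoefficientSet(**{f"c_{k}": float(v) for k, v in c.items()})


def cutoffs_from_config(cfg: dict) -> CutoffSet:
    c = cfg.get("cutoffs", {})
    return CutoffSet(
        t_low_mod=float(c["low_moderate"]),
        t_mod_high=float(c["moderate_high"]),
        t_high_vhigh=float(c["high_very_high"]),
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash used to stamp pipeline artifacts."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
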