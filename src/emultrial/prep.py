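"""Derivation of analysis variables from raw pupil rows.

Turns the cohort rectangle into the analysis table: exposure-scaled rates,
the persistent-absence flag (>= 10 % of possible half-day sessions missed
over follow-up), per-academic-year standardised Key Stage z-scores and
progress relative to school readiness, plus the eligibility / sensitivity
filters (Year-2 censoring, complete records).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_YEAR, N_YEARS

PERSISTENT_THRESHOLD = 0.10


def rate_per_1000(numerator, denominator):
    """Events per 1000 units of exposure; denominator must be positive."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if np.any(den <= 0):
        raise ValueError("rate denominator must be positive")
    return num / den * 1000.0


def flag_persistent(missed_sessions, possible_sessions, threshold: float = PERSISTENT_THRESHOLD):
    """True iff missed/possible >= threshold (boundary inclusive).

    Pupils with zero possible sessions have no defined absence outcome and
    get a missing flag (they drop out of the absence analyses).
    """
    missed = np.asarray(missed_sessions, dtype=float)
    possible = np.asarray(possible_sessions, dtype=float)
    out = np.where(possible > 0, missed >= threshold * possible, np.nan)
    if out.ndim == 0:
        return bool(out) if np.isfinite(out) else None
    return pd.array(
        [bool(v) if np.isfinite(v) else pd.NA for v in out], dtype="boolean"
    )


def dedupe_hospital_days(apc_day_set: Iterable, ae_day_set: Iterable) -> int:
    """Unplanned hospital days = size of the union of admitted and A&E days."""
    return len(set(apc_day_set) | set(ae_day_set))


def standardise_scores(raw_scores, academic_year) -> pd.Series:
    """Z-score within academic year (population SD); missing propagated.

    Mirrors scoring being standardised separately by test year to absorb
    marking variation; here the standardisation population is the cohort
    itself.
    """
    s = pd.Series(np.asarray(raw_scores, dtype=float))
    year = pd.Series(np.asarray(academic_year)).reindex(s.index)
    out = pd.Series(np.nan, index=s.index)
    for y, idx in s.groupby(year).groups.items():
        vals = s.loc[idx]
        obs = vals.dropna()
        if len(obs) == 0:
            continue  # nobody in this year group reached the assessment
        if len(obs) < 2:
            raise ValueError(f"need >=2 observed scores in year {y}")
        sd = obs.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero score variance in year {y}")
        out.loc[idx] = (vals - obs.mean()) / sd
    return out


def progress_score(ks_z, eyfsp_z):
    """Progress = attainment z minus school-readiness z; missing if either is."""
    return np.asarray(ks_z, dtype=float) - np.asarray(eyfsp_z, dtype=float)


def build_analysis_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach derived outcome columns to a cohort rectangle."""
    t = cohort.copy()
    t["rate_hosp"] = np.where(
        t["followup_years"] > 0,
        t["hospital_days_unplanned"] / t["followup_years"] * 1000.0,
        np.nan,
    )
    has_sess = t["sessions_possible"] > 0
    for col, num in (
        ("rate_medical", "sessions_medical"),
        ("rate_unauth", "sessions_unauthorised"),
    ):
        t[col] = np.where(has_sess, t[num] / t["sessions_possible"].where(has_sess) * 1000.0, np.nan)
    missed = t["sessions_medical"] + t["sessions_unauthorised"] + t.get(
        "sessions_other", 0
    )
    t["persistent_flag"] = flag_persistent(missed, t["sessions_possible"])
    for name in ("ks1", "ks2"):
        if f"{name}_raw" in t:
            t[f"{name}_z"] = standardise_scores(t[f"{name}_raw"], t["academic_year"])
            t[f"progress_{name}"] = progress_score(t[f"{name}_z"], t["eyfsp_z"])
    return t


def apply_mcim(
    table: pd.DataFrame,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Missing-covariate-indicator expansion of the raw covariates.

    Continuous covariates are zero-filled with a paired 0/1 indicator
    column; categorical covariates get an explicit ``"Unknown"`` level (the
    equivalent parameterisation).  Both value and indicator are meant to
    enter every downstream model.
    """
    t = table.copy()
    for name in continuous:
        flag_col = f"miss_{name}"
        miss = t[name].isna() if flag_col not in t else t[flag_col].astype(bool) | t[name].isna()
        t[flag_col] = miss.astype(int)
        t[name] = t[name].fillna(0.0)
    for name in categorical:
        col = t[name].astype(object)
        miss = pd.isna(col)
        col[miss] = "Unknown"
        t[name] = col
        t[f"miss_{name}"] = miss.astype(int)
    return t


def restrict_followup(cohort: pd.DataFrame, horizon_year: int = 2) -> pd.DataFrame:
    """Re-accumulate numerators and denominators up to the end of ``horizon_year``.

    Uses the per-year component columns the generator emits.  Key Stage 2
    outcomes are dropped for any horizon before Year 6.
    """
    if not 1 <= horizon_year <= N_YEARS:
        raise ValueError(f"horizon must be in 1..{N_YEARS}")
    t = cohort.copy()
    years = range(1, horizon_year + 1)
    agg = {
        "hospital_days_ae": "ae", "hospital_days_apc": "apc",
        "hospital_days_unplanned": "unpl", "sessions_medical": "med",
        "sessions_unauthorised": "una", "sessions_other": "oth",
    }
    for total, short in agg.items():
        t[total] = sum(t[f"{short}_y{k}"] for k in years)
    t["followup_years"] = sum(t[f"fu_y{k}"] for k in years)
    t["followup_days"] = np.round(t["followup_years"] * DAYS_PER_YEAR).astype(int)
    t["sessions_possible"] = sum(t[f"sess_y{k}"] for k in years)
    if horizon_year < N_YEARS and "ks2_raw" in t:
        t["ks2_raw"] = np.nan
    return t


def complete_records_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rows with no masked covariate; returns (subset, retained fraction)."""
    flags = [c for c in table.columns if c.startswith("miss_")]
    if not flags:
        raise ValueError("no missingness flags present")
    keep = (table[flags].sum(axis=1) == 0)
    if not keep.any():
        raise ValueError("complete-records filter removed every row")
    return table[keep].copy(), float(keep.mean())


def eligibility_filter(
    table: pd.DataFrame, flag_columns: Sequence[str] = ()
) -> pd.DataFrame:
    """Keep rows where every eligibility flag is truthy (pass-through).

    Eligibility phenotyping itself (diagnosis coding, school type) happens
    upstream; here flags are simply consumed.
    """
    keep = np.ones(len(table), dtype=bool)
    for col in flag_columns:
        keep &= table[col].astype(bool).to_numpy()
    return table[keep].copy()
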