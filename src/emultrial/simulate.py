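"""Clustered synthetic-cohort simulator with potential-outcome bookkeeping.

One simulated pupil carries: a local-authority cluster, a three-level SEN
exposure drawn from a multinomial-logistic law on the confounders, per-year
follow-up (entry in the January census of Year 1, exit at loss to follow-up,
end of study window for the pupil's academic cohort, or the end of Year 6),
per-year negative-binomial counts (A&E days, admitted days, medical /
unauthorised / other absence sessions) with person-time or session offsets,
and normally distributed Key Stage maths scores for pupils still enrolled
when the assessments happen.

Counts are generated as Poisson draws around a pupil-level gamma frailty
(shared across years), so each pupil's *total* over follow-up is marginally
NB2 with the configured dispersion while years remain positively correlated
within pupil.  Cluster-level normal intercepts on the link scale induce the
within-authority correlation that the cluster bootstrap must absorb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import GeneratorConfig, OutcomeSpec, TREATMENT_LEVELS

# follow-up geometry: entry at the January census of Year 1 leaves ~0.58 of
# a calendar year in Year 1; Years 2-6 are full years.  A full school year
# holds ~380 half-day sessions, the post-January part of Year 1 ~220.
N_YEARS = 6
YEAR_LENGTHS = np.array([0.58, 1.0, 1.0, 1.0, 1.0, 1.0])
SESSIONS_PER_YEAR = np.array([220, 380, 380, 380, 380, 380])
DAYS_PER_YEAR = 365.25
#: number of academic cohorts (index 0..10); cohort y has 10-y full years of
#: data after Year 1 before the study window closes
N_COHORTS = 11

#: probability that an A&E day and an admitted day coincide (same-day
#: presentations that are deduplicated in the analysed outcome)
P_SAME_DAY = 0.55

GEN_FEATURES = (
    "const", "male", "preterm_le34", "preterm_3536", "gest_3738",
    "bw_low", "bw_high", "mat_lt20", "mat_2024", "mat_3034", "mat_35p",
    "nonwhite", "noneng", "idaci_c", "fsm", "year_c",
    "cleft_palate", "cleft_uni", "cleft_bi", "chronic_any", "chronic_mental",
    "eyfsp_z", "relage_c", "prior_rate_c", "school_sen_c", "school_fsm_c",
    "nursery",
)

GEST_LEVELS = ("34 weeks or less", "35-36 weeks", "37-38 weeks", "39 weeks or more")
BW_LEVELS = ("Less than 2500g", "2500g-3499g", "3500g and higher")
MAT_LEVELS = ("<20", "20-24", "25-29", "30-34", "35 or higher")
CLEFT_LEVELS = ("Cleft lip only", "Cleft palate only", "Unilateral CLP", "Bilateral CLP")


def draw_covariates(n: int, n_clusters: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw raw confounders for ``n`` pupils across ``n_clusters`` authorities."""
    cluster_probs = rng.dirichlet(np.full(n_clusters, 6.0))
    cluster_id = rng.choice(n_clusters, size=n, p=cluster_probs)

    gender = np.where(rng.random(n) < 0.587, "Male", "Female")
    gest = rng.choice(GEST_LEVELS, size=n, p=[0.036, 0.047, 0.205, 0.712])
    bw = rng.choice(BW_LEVELS, size=n, p=[0.091, 0.533, 0.376])
    mat = rng.choice(MAT_LEVELS, size=n, p=[0.073, 0.211, 0.276, 0.263, 0.177])
    ethnic = np.where(rng.random(n) < 0.166, "Other", "White")
    language = np.where(rng.random(n) < 0.129, "Other", "English")
    idaci = rng.choice(
        [1, 2, 3, 4, 5], size=n, p=[0.264, 0.217, 0.194, 0.171, 0.154]
    ).astype(float)
    fsm_p = np.array([0.36, 0.22, 0.15, 0.10, 0.06])[idaci.astype(int) - 1]
    fsm = (rng.random(n) < fsm_p).astype(int)
    year_index = rng.choice(
        N_COHORTS,
        size=n,
        p=np.array([501, 550, 552, 568, 596, 622, 558, 639, 665, 654, 696]) / 6601.0,
    )
    cleft = rng.choice(CLEFT_LEVELS, size=n, p=[0.247, 0.437, 0.250, 0.066])
    chron_p = np.array([0.30, 0.46, 0.43, 0.50])
    cleft_code = pd.Categorical(cleft, categories=CLEFT_LEVELS).codes
    chronic_any = (rng.random(n) < chron_p[cleft_code]).astype(int)
    chronic_mental = ((rng.random(n) < 0.0905) & (chronic_any == 1)).astype(int)
    relage = rng.integers(0, 12, size=n)
    prior = rng.gamma(1.2, 1.6, size=n) * np.exp(0.5 * chronic_any)
    school_sen = rng.beta(2.5, 12.0, size=n)
    school_fsm = rng.beta(2.0, 8.0, size=n)
    nursery = (rng.random(n) < 0.4).astype(int)

    eyfsp = (
        0.32
        - 0.42 * chronic_any
        - 0.85 * chronic_mental
        - 0.28 * fsm
        + 0.07 * (idaci - 3)
        - 0.22 * (bw == BW_LEVELS[0])
        - 0.30 * (gest == GEST_LEVELS[0])
        + 0.05 * (relage - 5.5) / 3.452
        + rng.normal(0.0, 0.88, size=n)
    )

    return pd.DataFrame(
        {
            "pupil_id": np.arange(n),
            "cluster_id": cluster_id,
            "gender": gender,
            "gest_age": gest,
            "birthweight": bw,
            "maternal_age": mat,
            "ethnic_group": ethnic,
            "language": language,
            "idaci_quintile": idaci,
            "fsm": fsm,
            "academic_year": 2008 + year_index,
            "cleft_type": cleft,
            "chronic_any": chronic_any,
            "chronic_mental": chronic_mental,
            "eyfsp_z": eyfsp,
            "relative_age_months": relage,
            "prior_hosp_rate": prior,
            "school_sen_prop": school_sen,
            "school_fsm_prop": school_fsm,
            "nursery": nursery,
        }
    )


def generator_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Fixed numeric encoding of the raw covariates used by the generating laws."""
    n = len(cov)
    d = pd.DataFrame(index=cov.index)
    d["const"] = 1.0
    d["male"] = (cov["gender"] == "Male").astype(float)
    d["preterm_le34"] = (cov["gest_age"] == GEST_LEVELS[0]).astype(float)
    d["preterm_3536"] = (cov["gest_age"] == GEST_LEVELS[1]).astype(float)
    d["gest_3738"] = (cov["gest_age"] == GEST_LEVELS[2]).astype(float)
    d["bw_low"] = (cov["birthweight"] == BW_LEVELS[0]).astype(float)
    d["bw_high"] = (cov["birthweight"] == BW_LEVELS[2]).astype(float)
    d["mat_lt20"] = (cov["maternal_age"] == MAT_LEVELS[0]).astype(float)
    d["mat_2024"] = (cov["maternal_age"] == MAT_LEVELS[1]).astype(float)
    d["mat_3034"] = (cov["maternal_age"] == MAT_LEVELS[3]).astype(float)
    d["mat_35p"] = (cov["maternal_age"] == MAT_LEVELS[4]).astype(float)
    d["nonwhite"] = (cov["ethnic_group"] == "Other").astype(float)
    d["noneng"] = (cov["language"] == "Other").astype(float)
    d["idaci_c"] = cov["idaci_quintile"].astype(float) - 3.0
    d["fsm"] = cov["fsm"].astype(float)
    d["year_c"] = (cov["academic_year"].astype(float) - 2013.0) / 5.0
    d["cleft_palate"] = (cov["cleft_type"] == CLEFT_LEVELS[1]).astype(float)
    d["cleft_uni"] = (cov["cleft_type"] == CLEFT_LEVELS[2]).astype(float)
    d["cleft_bi"] = (cov["cleft_type"] == CLEFT_LEVELS[3]).astype(float)
    d["chronic_any"] = cov["chronic_any"].astype(float)
    d["chronic_mental"] = cov["chronic_mental"].astype(float)
    d["eyfsp_z"] = cov["eyfsp_z"].astype(float)
    d["relage_c"] = (cov["relative_age_months"].astype(float) - 5.5) / 3.452
    d["prior_rate_c"] = np.log1p(cov["prior_hosp_rate"].astype(float)) - 1.0
    d["school_sen_c"] = cov["school_sen_prop"].astype(float) - 0.17
    d["school_fsm_c"] = cov["school_fsm_prop"].astype(float) - 0.20
    d["nursery"] = cov["nursery"].astype(float)
    assert list(d.columns) == list(GEN_FEATURES)
    return d


def _linpred(design: pd.DataFrame, coef: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(design))
    for name, value in coef.items():
        if name not in design.columns:
            raise ValueError(f"coefficient on unknown design feature {name!r}")
        lp += value * design[name].to_numpy()
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    return lp


def treatment_probabilities(
    design: pd.DataFrame, ps_coefficients: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Multinomial-logit assignment probabilities, reference level ``None``."""
    logits = np.zeros((len(design), len(TREATMENT_LEVELS)))
    for j, lev in enumerate(TREATMENT_LEVELS[1:], start=1):
        logits[:, j] = _linpred(design, ps_coefficients.get(lev, {}))
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, columns=list(TREATMENT_LEVELS), index=design.index)


def assign_treatment(
    design: pd.DataFrame,
    ps_coefficients: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one of the three levels per row from the multinomial-logit law."""
    probs = treatment_probabilities(design, ps_coefficients).to_numpy()
    u = rng.random(len(design))
    cum = probs.cumsum(axis=1)
    idx = (u[:, None] >= cum).sum(axis=1)
    return np.asarray(TREATMENT_LEVELS, dtype=object)[idx]


def draw_followup(
    year_index: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> dict:
    """Per-year participation, person-time and possible sessions.

    Year 1 (post-January) is always observed.  Each later year is observed
    only if the study window for the pupil's academic cohort still covers it
    and the pupil was not lost to follow-up at a preceding year boundary.
    """
    n = len(year_index)
    max_post = np.minimum(N_YEARS - 1, (N_COHORTS - 1) - year_index)  # cohorts end study
    dropout = rng.random((n, N_YEARS - 1)) < config.dropout_rate
    survived = np.cumprod(~dropout, axis=1)  # still enrolled entering year k+1
    participate = np.zeros((n, N_YEARS), dtype=bool)
    participate[:, 0] = True
    for k in range(1, N_YEARS):
        participate[:, k] = (k <= max_post) & survived[:, k - 1].astype(bool)
    fu_years = participate * YEAR_LENGTHS
    sessions = (participate * SESSIONS_PER_YEAR).astype(int)
    no_absence = rng.random(n) < config.p_no_absence_data
    sessions[no_absence] = 0
    return {
        "participate": participate,
        "fu_years": fu_years,
        "sessions": sessions,
        "no_absence": no_absence,
    }


def draw_shared_noise(
    config: GeneratorConfig,
    n: int,
    cluster_id: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Cluster intercepts, pupil frailties and score residuals.

    These are shared between potential outcomes under different arms, so the
    oracle can evaluate counterfactual pairs on common noise.
    """
    noise: dict[str, dict[str, np.ndarray]] = {"cluster": {}, "frailty": {}, "eps": {}}
    for name, spec in config.outcome_specs.items():
        ce = rng.normal(0.0, spec.cluster_sd, size=config.n_clusters)
        noise["cluster"][name] = ce[cluster_id]
        if spec.family == "count":
            alpha = spec.dispersion
            noise["frailty"][name] = rng.gamma(1.0 / alpha, alpha, size=n)
        elif spec.family == "normal":
            noise["eps"][name] = rng.normal(0.0, spec.dispersion, size=n)
    return noise


def _year_marking(year_index: np.ndarray, which: str) -> tuple[np.ndarray, np.ndarray]:
    # deterministic year-to-year marking drift, removed by standardisation
    shift = 0.25 * np.sin(year_index + (1.0 if which == "ks2" else 0.0))
    scale = 1.0 + 0.06 * (year_index % 3)
    return shift, scale


def simulate_outcomes(
    design: pd.DataFrame,
    treatment: np.ndarray,
    config: GeneratorConfig,
    followup: dict,
    noise: dict,
    rng: np.random.Generator,
    year_index: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Draw all outcome numerators and scores for the given assignment.

    Count outcomes are Poisson draws around ``offset * exp(lp) * frailty``
    per observed year; raw Key Stage scores are emitted only for pupils
    enrolled in the assessment year (Year 2 for KS1, Year 6 for KS2).
    """
    n = len(design)
    out = pd.DataFrame(index=design.index)
    fu, sess = followup["fu_years"], followup["sessions"]
    if np.any(fu < 0):
        raise ValueError("negative offsets")
    te = {
        name: np.array([spec.effect(a) for a in treatment])
        for name, spec in config.outcome_specs.items()
    }

    counts: dict[str, np.ndarray] = {}
    for name, spec in config.outcome_specs.items():
        if spec.family != "count":
            continue
        rate = np.exp(_linpred(design, spec.coef) + noise["cluster"][name] + te[name])
        lam = rate * noise["frailty"][name]
        offs = fu if spec.offset == "followup" else sess
        counts[name] = rng.poisson(lam[:, None] * offs)

    # same-day A&E / admission overlap, deduplicated unplanned total
    ae, apc = counts["hospital_ae"], counts["hospital_apc"]
    overlap = rng.binomial(np.minimum(ae, apc), P_SAME_DAY)
    unplanned = ae + apc - overlap
    cap = np.floor(fu * DAYS_PER_YEAR).astype(int)
    unplanned = np.minimum(unplanned, cap)
    overlap = ae + apc - unplanned  # keep the accounting identity after capping

    # absence counts cannot exceed possible sessions
    med, una, oth = (
        counts["medical_absence"],
        counts["unauthorised_absence"],
        counts["other_absence"],
    )
    med = np.minimum(med, sess)
    una = np.minimum(una, sess - med)
    oth = np.minimum(oth, sess - med - una)

    per_year = {
        "ae": ae, "apc": apc, "unpl": unplanned,
        "med": med, "una": una, "oth": oth,
    }
    for short, arr in per_year.items():
        for k in range(N_YEARS):
            out[f"{short}_y{k + 1}"] = arr[:, k]
    for k in range(N_YEARS):
        out[f"fu_y{k + 1}"] = fu[:, k]
        out[f"sess_y{k + 1}"] = sess[:, k]

    out["hospital_days_ae"] = ae.sum(axis=1)
    out["hospital_days_apc"] = apc.sum(axis=1)
    out["hospital_days_unplanned"] = unplanned.sum(axis=1)
    out["followup_years"] = fu.sum(axis=1)
    out["followup_days"] = np.round(out["followup_years"] * DAYS_PER_YEAR).astype(int)
    out["sessions_possible"] = sess.sum(axis=1)
    out["sessions_medical"] = med.sum(axis=1)
    out["sessions_unauthorised"] = una.sum(axis=1)
    out["sessions_other"] = oth.sum(axis=1)

    if year_index is None:
        year_index = np.zeros(n, dtype=int)
    for name in ("ks1", "ks2"):
        spec = config.outcome_specs.get(name)
        if spec is None:
            continue
        mu = _linpred(design, spec.coef) + noise["cluster"][name] + te[name]
        z_latent = mu + noise["eps"][name]
        shift, scale = _year_marking(year_index, name)
        raw = shift + scale * z_latent
        reached = followup["participate"][:, 1 if name == "ks1" else 5]
        out[f"{name}_raw"] = np.where(reached, raw, np.nan)

    # optional direct-logistic persistent absence (power experiments)
    if config.persistent_mode == "direct" and "persistent" in config.outcome_specs:
        spec = config.outcome_specs["persistent"]
        from scipy.special import expit

        p = expit(_linpred(design, spec.coef) + noise["cluster"]["persistent"] + te["persistent"])
        out["persistent_direct"] = (rng.random(n) < p).astype(int)
    return out


def conditional_mean_rates(
    design: pd.DataFrame,
    config: GeneratorConfig,
    noise: dict,
    level: str,
) -> pd.DataFrame:
    """Conditional mean rates / score means under assignment to ``level``.

    Count outcomes: frailty-inclusive rate per unit offset.  Normal
    outcomes: latent z-scale potential score including the shared residual.
    """
    res = pd.DataFrame(index=design.index)
    for name, spec in config.outcome_specs.items():
        lp = _linpred(design, spec.coef) + noise["cluster"][name] + spec.effect(level)
        if spec.family == "count":
            res[name] = np.exp(lp) * noise["frailty"][name]
        elif spec.family == "normal":
            res[name] = lp + noise["eps"][name]
    return res


def impose_missingness(
    df: pd.DataFrame,
    missingness: dict,
    rng: np.random.Generator,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Mask covariate values MAR and set ``miss_*`` indicator columns.

    The masking log-odds are the configured coefficients on fully observed
    design features plus an intercept solved (per draw) so the empirical
    masking fraction matches the configured marginal rate.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    df = df.copy()
    if design is None:
        design = generator_design(df)
    for name, spec in missingness.items():
        if name not in df.columns:
            raise ValueError(f"missingness spec references unknown covariate {name!r}")
        flag = np.zeros(len(df), dtype=int)
        if spec.rate > 0:
            lp = _linpred(design, spec.coef)
            if np.allclose(lp, lp[0]):
                c = float(np.log(spec.rate / (1 - spec.rate)) - lp[0])
            else:
                c = brentq(
                    lambda c_: expit(lp + c_).mean() - spec.rate, -30.0, 30.0
                )
            flag = (rng.random(len(df)) < expit(lp + c)).astype(int)
        mask = flag.astype(bool)
        if pd.api.types.is_numeric_dtype(df[name]):
            df.loc[mask, name] = np.nan
        else:
            col = df[name].astype(object)
            col[mask] = np.nan
            df[name] = col
        df[f"miss_{name}"] = flag
    return df


@dataclass
class Cohort:
    """Generated cohort: emitted data plus internal potential-outcome truth."""

    data: pd.DataFrame
    potential: pd.DataFrame
    config: GeneratorConfig
    seed: Optional[int]

    def __len__(self) -> int:
        return len(self.data)


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> Cohort:
    """Generate a full synthetic cohort under ``config``.

    Stage seeds are spawned from the root seed, so identical config + seed
    reproduces the cohort exactly.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    r_cov, r_trt, r_fu, r_noise, r_out, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    cov = draw_covariates(config.n_pupils, config.n_clusters, r_cov)
    design = generator_design(cov)
    probs = treatment_probabilities(design, config.ps_coefficients)
    treatment = assign_treatment(design, config.ps_coefficients, r_trt)
    year_index = cov["academic_year"].to_numpy() - 2008
    followup = draw_followup(year_index, config, r_fu)
    noise = draw_shared_noise(config, config.n_pupils, cov["cluster_id"].to_numpy(), r_noise)
    outcomes = simulate_outcomes(
        design, treatment, config, followup, noise, r_out, year_index=year_index
    )

    data = pd.concat([cov, outcomes], axis=1)
    data.insert(2, "treatment", treatment)
    data = impose_missingness(data, config.missingness, r_miss, design=design)

    potential = pd.DataFrame({"treatment": treatment}, index=cov.index)
    for lev in TREATMENT_LEVELS:
        potential[f"p_{lev}"] = probs[lev]
        cm = conditional_mean_rates(design, config, noise, lev)
        for name in cm.columns:
            potential[f"{name}:{lev}"] = cm[name]
    if len(data) != config.n_pupils:
        raise AssertionError("generator emitted wrong number of records")
    return Cohort(data=data, potential=potential, config=config, seed=seed)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, csv_path, sidecar_path=None) -> None:
    """Write the pupil rectangle as CSV plus a JSON sidecar (config + seed)."""
    cohort.data.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"seed": cohort.seed, "config": cohort.config.to_dict()},
                fh,
                indent=1,
                default=float,
            )


def read_cohort(csv_path) -> pd.DataFrame:
    """Read a cohort CSV, keeping the literal string ``"None"`` as a level."""
    df = pd.read_csv(csv_path, keep_default_na=False, na_values=[""])
    return df
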