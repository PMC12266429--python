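"""Generator configuration for clustered synthetic pupil cohorts.

The synthetic cohort emulates the analysis-ready rectangle of a national
linked education/health cohort of children with an isolated orofacial cleft:
one row per pupil, a three-level special-educational-needs (SEN) exposure
recorded in Year 1 (``None`` / ``Support`` / ``EHCP``), a local-authority
cluster identifier, the confounders of the study's descriptive table, and
count / binary / continuous outcomes accumulated over primary school with
person-time or session offsets.

Coefficients are expressed on the link scale against the *generator design*
(see :func:`emultrial.simulate.generator_design`), a fixed numeric encoding
of the covariates.  Defaults are calibrated so that arm shares, outcome
rates, persistent-absence prevalence and missingness margins match the
published cohort margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

TREATMENT_LEVELS = ("None", "Support", "EHCP")

#: outcome families understood by the simulator
FAMILIES = ("count", "binary", "normal")

#: offset laws for count outcomes
OFFSETS = ("followup", "sessions", None)


@dataclass
class OutcomeSpec:
    """One simulated outcome: family, linear predictor, treatment effects.

    For ``count`` outcomes the mean is ``offset * exp(lp)`` and
    ``dispersion`` is the negative-binomial (NB2) dispersion ``alpha``
    (variance ``mu + alpha*mu^2``; ``alpha -> 0`` recovers Poisson).
    For ``normal`` outcomes ``dispersion`` is the residual SD.
    ``treatment_effects`` are on the link scale with ``None`` as reference.
    """

    name: str
    family: str
    coef: dict[str, float]
    treatment_effects: dict[str, float]
    dispersion: float = 1.0
    cluster_sd: float = 0.2
    offset: Optional[str] = None

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown outcome family {self.family!r} for {self.name}")
        if self.offset not in OFFSETS:
            raise ValueError(f"unknown offset law {self.offset!r} for {self.name}")
        if self.family == "count" and self.offset is None:
            raise ValueError(f"count outcome {self.name} needs an offset law")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0 for {self.name}")
        if self.cluster_sd < 0:
            raise ValueError(f"cluster_sd must be >= 0 for {self.name}")
        for lev in self.treatment_effects:
            if lev not in TREATMENT_LEVELS:
                raise ValueError(f"unknown treatment level {lev!r} in {self.name}")

    def effect(self, level: str) -> float:
        return float(self.treatment_effects.get(level, 0.0))


@dataclass
class MissingnessSpec:
    """MAR masking law for one covariate.

    ``rate`` is the marginal masking probability; ``coef`` are log-odds
    coefficients on fully observed generator-design features (the intercept
    is solved so the empirical rate matches ``rate``).
    """

    rate: float
    coef: dict[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"missingness rate for {name} must be in [0,1)")


@dataclass
class GeneratorConfig:
    n_pupils: int = 6601
    n_clusters: int = 150
    ps_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_specs: dict[str, OutcomeSpec] = field(default_factory=dict)
    missingness: dict[str, MissingnessSpec] = field(default_factory=dict)
    #: yearly probability of loss to follow-up after each completed year
    dropout_rate: float = 0.025
    #: probability a pupil has no usable absence records at all
    p_no_absence_data: float = 0.0008
    #: "derived" computes persistent absence from simulated sessions;
    #: "direct" adds an independent logistic draw (power experiments)
    persistent_mode: str = "derived"
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_pupils <= 0:
            raise ValueError("n_pupils must be positive")
        if not 0 < self.n_clusters <= self.n_pupils:
            raise ValueError("need 0 < n_clusters <= n_pupils")
        for lev in self.ps_coefficients:
            if lev not in TREATMENT_LEVELS[1:]:
                raise ValueError(
                    f"ps_coefficients keyed by non-reference level, got {lev!r}"
                )
        for spec in self.outcome_specs.values():
            spec.validate()
        for name, spec in self.missingness.items():
            spec.validate(name)
        if self.persistent_mode not in ("derived", "direct"):
            raise ValueError("persistent_mode must be 'derived' or 'direct'")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["outcome_specs"] = {
            k: OutcomeSpec(**v) if not isinstance(v, OutcomeSpec) else v
            for k, v in d.get("outcome_specs", {}).items()
        }
        d["missingness"] = {
            k: MissingnessSpec(**v) if not isinstance(v, MissingnessSpec) else v
            for k, v in d.get("missingness", {}).items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Default (study-condition) configuration
# ---------------------------------------------------------------------------

# Assignment law, log-odds vs "None".  Intercepts calibrated so the default
# covariate mix yields arm shares near 65.9 / 30.4 / 3.7 %.
_PS_SUPPORT = {
    "const": -1.875,
    "male": 0.30,
    "preterm_le34": 0.45,
    "preterm_3536": 0.22,
    "gest_3738": 0.18,
    "bw_low": 0.40,
    "bw_high": -0.18,
    "mat_lt20": 0.30,
    "mat_2024": 0.22,
    "mat_3034": -0.12,
    "mat_35p": -0.08,
    "nonwhite": 0.08,
    "noneng": 0.05,
    "idaci_c": -0.16,
    "fsm": 0.45,
    "year_c": -0.28,
    "cleft_palate": 0.45,
    "cleft_uni": 0.62,
    "cleft_bi": 0.75,
    "chronic_any": 0.40,
    "chronic_mental": 0.95,
    "eyfsp_z": -0.85,
    "relage_c": -0.15,
    "prior_rate_c": 0.12,
    "school_sen_c": 1.2,
    "school_fsm_c": 0.4,
}

_PS_EHCP = {
    "const": -5.396,
    "male": 0.55,
    "preterm_le34": 1.00,
    "preterm_3536": 0.30,
    "gest_3738": 0.20,
    "bw_low": 0.80,
    "bw_high": -0.35,
    "mat_lt20": 0.10,
    "mat_2024": 0.05,
    "mat_3034": 0.10,
    "mat_35p": 0.15,
    "nonwhite": 0.25,
    "noneng": 0.15,
    "idaci_c": 0.05,
    "fsm": 0.15,
    "year_c": -0.15,
    "cleft_palate": 0.90,
    "cleft_uni": 0.45,
    "cleft_bi": 1.10,
    "chronic_any": 0.90,
    "chronic_mental": 2.40,
    "eyfsp_z": -1.55,
    "relage_c": -0.10,
    "school_sen_c": 1.2,
}

# Outcome linear predictors (log-rate for counts, score scale for normals).
_HOSP_SHARED = {
    "chronic_any": 0.55,
    "chronic_mental": 0.25,
    "preterm_le34": 0.35,
    "bw_low": 0.28,
    "eyfsp_z": -0.10,
    "fsm": 0.18,
    "idaci_c": -0.07,
    "cleft_palate": 0.20,
    "cleft_uni": 0.12,
    "cleft_bi": 0.25,
    "prior_rate_c": 0.40,
}

_ABSENCE_SHARED = {
    "chronic_any": 0.30,
    "chronic_mental": 0.20,
    "eyfsp_z": -0.08,
    "fsm": 0.15,
    "idaci_c": -0.06,
    "cleft_palate": 0.10,
    "prior_rate_c": 0.12,
}


def _default_outcomes() -> dict[str, OutcomeSpec]:
    import math

    return {
        # unplanned hospital care, split by pathway; the analysed outcome
        # (total unplanned days, same-day A&E/admission deduplicated) is
        # derived from these two plus a simulated overlap
        "hospital_ae": OutcomeSpec(
            name="hospital_ae",
            family="count",
            coef={"const": -2.143, **_HOSP_SHARED},
            treatment_effects={"Support": 0.0, "EHCP": 0.35},
            dispersion=2.5,
            cluster_sd=0.2,
            offset="followup",
        ),
        "hospital_apc": OutcomeSpec(
            name="hospital_apc",
            family="count",
            coef={"const": -2.473, **_HOSP_SHARED},
            treatment_effects={"Support": 0.0, "EHCP": 0.45},
            dispersion=3.5,
            cluster_sd=0.2,
            offset="followup",
        ),
        "medical_absence": OutcomeSpec(
            name="medical_absence",
            family="count",
            coef={"const": -3.645, **_ABSENCE_SHARED},
            treatment_effects={"Support": math.log(1.09), "EHCP": math.log(1.25)},
            dispersion=0.35,
            cluster_sd=0.15,
            offset="sessions",
        ),
        "unauthorised_absence": OutcomeSpec(
            name="unauthorised_absence",
            family="count",
            coef={
                "const": -4.905,
                "fsm": 0.55,
                "idaci_c": -0.18,
                "noneng": 0.15,
                "chronic_any": 0.10,
                "eyfsp_z": -0.06,
            },
            treatment_effects={"Support": math.log(0.90), "EHCP": math.log(0.95)},
            dispersion=1.0,
            cluster_sd=0.15,
            offset="sessions",
        ),
        # other (non-medical authorised etc.) absences: only feed the
        # persistent-absence functional, never analysed directly
        "other_absence": OutcomeSpec(
            name="other_absence",
            family="count",
            coef={"const": -4.227, "fsm": 0.12, "idaci_c": -0.05},
            treatment_effects={},
            dispersion=0.25,
            cluster_sd=0.1,
            offset="sessions",
        ),
        # raw maths scores; year-specific marking drift is added on top and
        # removed again by per-year standardisation downstream
        "ks1": OutcomeSpec(
            name="ks1",
            family="normal",
            coef={
                "const": 0.18,
                "eyfsp_z": 0.48,
                "fsm": -0.18,
                "idaci_c": 0.05,
                "chronic_any": -0.12,
                "chronic_mental": -0.30,
                "male": -0.05,
                "relage_c": 0.06,
            },
            treatment_effects={"Support": -0.21, "EHCP": -0.55},
            dispersion=0.78,
            cluster_sd=0.1,
            offset=None,
        ),
        "ks2": OutcomeSpec(
            name="ks2",
            family="normal",
            coef={
                "const": 0.20,
                "eyfsp_z": 0.44,
                "fsm": -0.20,
                "idaci_c": 0.06,
                "chronic_any": -0.12,
                "chronic_mental": -0.32,
                "male": -0.02,
                "relage_c": 0.04,
            },
            treatment_effects={"Support": -0.27, "EHCP": -0.60},
            dispersion=0.82,
            cluster_sd=0.1,
            offset=None,
        ),
    }


def _default_missingness() -> dict[str, MissingnessSpec]:
    # marginal rates follow the published "Unknown" fractions; MAR drivers
    # are fully observed covariates (earlier cohorts have poorer birth data)
    return {
        "gest_age": MissingnessSpec(rate=0.227, coef={"year_c": -0.9, "fsm": 0.2}),
        "birthweight": MissingnessSpec(rate=0.166, coef={"year_c": -0.9, "fsm": 0.2}),
        "maternal_age": MissingnessSpec(rate=0.040, coef={"year_c": -0.5, "nonwhite": 0.3}),
        "idaci_quintile": MissingnessSpec(rate=0.002, coef={}),
        "eyfsp_z": MissingnessSpec(rate=0.009, coef={"chronic_any": 0.4}),
    }


def reduced_config(
    n_pupils: int = 10_000,
    n_clusters: int = 100,
    hospital_effect: float = 0.0,
    seed: Optional[int] = None,
) -> GeneratorConfig:
    """Small-confounder configuration whose analysis models can be exactly
    correctly specified.

    Assignment and outcomes depend only on free-school-meal eligibility,
    chronic condition and the school-readiness z-score — all represented
    linearly (or as saturated dummies) in the analysis design — and no
    covariate is masked.  Used for double-robustness and coverage
    experiments where "correct model" must mean exactly that.
    """
    import math

    feats = {"fsm": 0.6, "chronic_any": 0.7, "eyfsp_z": -0.8}
    outcomes = _default_outcomes()
    for name, spec in outcomes.items():
        keep = {"const": spec.coef["const"]}
        keep.update(
            {
                "fsm": 0.25 if spec.family == "count" else -0.2,
                "chronic_any": 0.45 if spec.family == "count" else -0.15,
                "eyfsp_z": -0.12 if spec.family == "count" else 0.45,
            }
        )
        spec.coef = keep
        spec.cluster_sd = min(spec.cluster_sd, 0.15)
    for name in ("hospital_ae", "hospital_apc"):
        outcomes[name].treatment_effects = {"Support": hospital_effect, "EHCP": 0.3}
    cfg = GeneratorConfig(
        n_pupils=n_pupils,
        n_clusters=n_clusters,
        ps_coefficients={
            "Support": {"const": -0.95, **feats},
            "EHCP": {"const": -4.2, **{k: 1.5 * v for k, v in feats.items()}},
        },
        outcome_specs=outcomes,
        missingness={},
        seed=seed,
    )
    cfg.validate()
    return cfg


def default_config(
    n_pupils: int = 6601,
    n_clusters: int = 150,
    seed: Optional[int] = None,
    null_effects: bool = False,
) -> GeneratorConfig:
    """Study-condition generator configuration.

    ``null_effects=True`` zeroes every treatment effect (all ratio truths 1,
    all difference truths 0) while keeping the confounded assignment law, so
    crude contrasts remain biased — the canonical null-preservation setup.
    """
    outcomes = _default_outcomes()
    if null_effects:
        for spec in outcomes.values():
            spec.treatment_effects = {}
    cfg = GeneratorConfig(
        n_pupils=n_pupils,
        n_clusters=n_clusters,
        ps_coefficients={"Support": dict(_PS_SUPPORT), "EHCP": dict(_PS_EHCP)},
        outcome_specs=outcomes,
        missingness=_default_missingness(),
        seed=seed,
    )
    cfg.validate()
    return cfg
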