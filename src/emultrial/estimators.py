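"""Crude, conditional, IPW, g-computation and AIPW effect estimation.

Every estimate is an :class:`EffectEstimate`: outcome x contrast x estimand
(crude / conditional / ATE / ATT) x estimator on the outcome's reporting
scale — rate ratios (RaR) for count outcomes with person-time or session
offsets, risk ratios (RiR) for persistent absence (odds ratio for the crude
row, following the conventional layout), mean differences (Delta) for
standardised scores.

Point estimates here carry no intervals; cluster-aware CIs come from the
uncertainty module, which re-runs the full chain per bootstrap replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .design import CovariateSpec, build_design, drop_collinear
from .propensity import (
    PropensityResult,
    TreatmentContrast,
    fit_ps_model,
    lasso_select,
    subset_contrast,
)

#: analysed outcomes: family, numerator / value column, exposure column
OUTCOMES: dict[str, dict] = {
    "hospital": dict(family="negbin", num="hospital_days_unplanned", exposure="followup_years"),
    "hospital_ae": dict(family="negbin", num="hospital_days_ae", exposure="followup_years"),
    "hospital_apc": dict(family="negbin", num="hospital_days_apc", exposure="followup_years"),
    "medical_absence": dict(family="negbin", num="sessions_medical", exposure="sessions_possible"),
    "unauthorised_absence": dict(
        family="negbin", num="sessions_unauthorised", exposure="sessions_possible"
    ),
    "persistent": dict(family="logistic", num="persistent_flag", exposure=None),
    "ks1": dict(family="linear", num="ks1_z", exposure=None),
    "ks2": dict(family="linear", num="ks2_z", exposure=None),
    "progress_ks1": dict(family="linear", num="progress_ks1", exposure=None),
    "progress_ks2": dict(family="linear", num="progress_ks2", exposure=None),
}

_MEASURES = {"negbin": "RaR", "poisson": "RaR", "logistic": "RiR", "linear": "Delta"}


@dataclass
class EffectEstimate:
    outcome: str
    contrast: TreatmentContrast
    estimand: str  # crude | conditional | ATE | ATT
    estimator: str  # regression | IPW | gcomp | AIPW
    measure: str  # RaR | RiR | OR | Delta
    point: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_used: int = 0
    diagnostics: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "contrast": str(self.contrast),
            "estimand": self.estimand,
            "estimator": self.estimator,
            "measure": self.measure,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_used,
        }


@dataclass
class WeightSet:
    estimand: str
    weights: pd.Series

    @property
    def max_weight(self) -> float:
        return float(self.weights.max())

    @property
    def effective_n(self) -> float:
        w = self.weights.to_numpy()
        return float(w.sum() ** 2 / np.sum(w**2))


def ipw_weights(ps, exposed_indicator, estimand: str = "ATE") -> WeightSet:
    """Inverse-probability weights for ATE or ATT.

    ATE: exposed 1/ps, reference 1/(1-ps).  ATT: exposed 1, reference
    ps/(1-ps) (re-weights the reference arm to the exposed covariate mix).
    """
    ps = pd.Series(ps)
    a = pd.Series(exposed_indicator).astype(int)
    if ((ps <= 0) | (ps >= 1)).any():
        raise ValueError("propensity score at 0 or 1: positivity violation")
    if estimand == "ATE":
        w = np.where(a == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    elif estimand == "ATT":
        w = np.where(a == 1, 1.0, ps / (1.0 - ps))
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    return WeightSet(estimand=estimand, weights=pd.Series(w, index=ps.index))


# ---------------------------------------------------------------------------
# outcome model fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedOutcome:
    result: object
    family: str
    nb_alpha: Optional[float] = None

    def predict_rate(self, X: pd.DataFrame) -> np.ndarray:
        """Mean response per unit exposure (offset excluded)."""
        eta = X.to_numpy(dtype=float) @ np.asarray(self.result.params)
        link = self.result.model.family.link
        return np.asarray(link.inverse(eta))


def _nb_loglik(y, X, log_exposure, weights, alpha):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fam = sm.families.NegativeBinomial(alpha=alpha)
        res = sm.GLM(y, X, family=fam, offset=log_exposure, var_weights=weights).fit(
            maxiter=200, wls_method="qr"
        )
    return res, res.llf


def fit_outcome_model(
    y,
    X: pd.DataFrame,
    family: str,
    exposure=None,
    weights=None,
    nb_alpha: Optional[float] = None,
) -> FittedOutcome:
    """(Weighted) ML fit of the outcome family.

    ``exposure`` is the raw exposure (person-years / sessions); its log is
    the model offset for count families.  The NB dispersion is profiled by
    ML on the log scale (tolerance 1e-8) unless ``nb_alpha`` pins it; a
    profile optimum at ~0 overdispersion warns and falls back to Poisson.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1 and np.nanstd(y) == 0:
        raise ValueError("zero-variance outcome")
    w = None if weights is None else np.asarray(weights, dtype=float)
    log_exp = None
    if family in ("negbin", "poisson"):
        if exposure is None:
            raise ValueError("count families need an exposure offset")
        exposure = np.asarray(exposure, dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("exposure offsets must be positive")
        log_exp = np.log(exposure)

    if family == "negbin":
        if nb_alpha is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")

                def negll(log_a):
                    return -_nb_loglik(y, X, log_exp, w, float(np.exp(log_a)))[1]

                opt = minimize_scalar(
                    negll, bounds=(-12.0, 3.5), method="bounded",
                    options={"xatol": 1e-8},
                )
            nb_alpha = float(np.exp(opt.x))
        if nb_alpha < 1e-5:
            warnings.warn("estimated overdispersion ~0; falling back to Poisson")
            family = "poisson"
        else:
            res, _ = _nb_loglik(y, X, log_exp, w, nb_alpha)
            return FittedOutcome(res, "negbin", nb_alpha=nb_alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            res = sm.GLM(
                y, X, family=sm.families.Poisson(), offset=log_exp, var_weights=w
            ).fit(maxiter=200, wls_method="qr")
            return FittedOutcome(res, "poisson")
        if family == "logistic":
            res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
                maxiter=200, wls_method="qr"
            )
            return FittedOutcome(res, "logistic")
        if family == "linear":
            res = sm.WLS(y, X, weights=1.0 if w is None else w).fit(method="qr")
            return FittedOutcome(res, "linear")
    raise ValueError(f"unknown outcome family {family!r}")




def _counterfactual_designs(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Copies of the design with treatment set to 1 and 0.

    Columns named ``treat_x_<name>`` are treatment interactions and are
    recomputed as ``treat * <name>`` under each counterfactual arm, so a
    saturated (fully interacted) outcome model standardises exactly.
    """
    Xe, Xr = X.copy(), X.copy()
    Xe["treat"], Xr["treat"] = 1.0, 0.0
    for col in X.columns:
        if col.startswith("treat_x_"):
            base = col[len("treat_x_"):]
            if base not in X.columns:
                raise ValueError(f"interaction {col} lacks main-effect column {base}")
            Xe[col] = X[base]
            Xr[col] = 0.0
    return Xe, Xr




# linear results have no GLM family; patch predict_rate for them
def _linear_predict_rate(self, X):  # pragma: no cover - tiny shim
    return X.to_numpy(dtype=float) @ np.asarray(self.result.params)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _outcome_frame(table: pd.DataFrame, outcome: str, contrast: TreatmentContrast):
    """Two-arm subset restricted to rows where the outcome is defined."""
    meta = OUTCOMES[outcome]
    sub = subset_contrast(table, contrast)
    if meta["family"] in ("negbin", "poisson"):
        ok = sub[meta["exposure"]] > 0
    elif outcome == "persistent":
        ok = sub[meta["num"]].notna()
    else:
        ok = sub[meta["num"]].notna()
    sub = sub[ok].copy()
    a = (sub["treatment"] == contrast.exposed).astype(int)
    if meta["family"] == "logistic":
        yv = sub[meta["num"]].astype("boolean").astype("Int64").astype(float)
        y = np.asarray(yv, dtype=float)
    else:
        y = sub[meta["num"]].to_numpy(dtype=float)
    exposure = None if meta["exposure"] is None else sub[meta["exposure"]].to_numpy(dtype=float)
    return sub, y, a, exposure, meta


def _ratio_family(meta, family_override):
    return family_override or meta["family"]


def _treatment_design(a: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({"const": 1.0, "treat": a.astype(float)}, index=a.index)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_crude(
    table: pd.DataFrame,
    outcome: str,
    contrast: TreatmentContrast,
    family: Optional[str] = None,
) -> EffectEstimate:
    """Treatment-only model; exponentiated coefficient on ratio scales.

    For the binary outcome the crude contrast is the odds ratio from the
    treatment-only logistic fit (the conventional crude row); causal rows
    report risk ratios instead.
    """
    sub, y, a, exposure, meta = _outcome_frame(table, outcome, contrast)
    fam = _ratio_family(meta, family)
    X = _treatment_design(a)
    fit = fit_outcome_model(y, X, fam, exposure=exposure)
    coef = float(fit.result.params["treat"])
    if fam == "linear":
        point, measure = coef, "Delta"
    elif fam == "logistic":
        point, measure = float(np.exp(coef)), "OR"
    else:
        point, measure = float(np.exp(coef)), "RaR"
    return EffectEstimate(
        outcome, contrast, "crude", "regression", measure, point,
        n_used=len(sub), diagnostics={"family": fit.family, "nb_alpha": fit.nb_alpha},
    )


def estimate_conditional(
    table: pd.DataFrame,
    outcome: str,
    contrast: TreatmentContrast,
    spec: Optional[CovariateSpec] = None,
    family: Optional[str] = None,
) -> EffectEstimate:
    """Full-covariate (MCIM design) model; treatment coefficient reported."""
    sub, y, a, exposure, meta = _outcome_frame(table, outcome, contrast)
    fam = _ratio_family(meta, family)
    X = build_design(sub, spec=spec, quadratic=False)
    X.insert(1, "treat", a.astype(float))
    X = drop_collinear(X)
    fit = fit_outcome_model(y, X, fam, exposure=exposure)
    coef = float(fit.result.params["treat"])
    if fam == "linear":
        point, measure = coef, "Delta"
    elif fam == "logistic":
        point, measure = float(np.exp(coef)), "OR"
    else:
        point, measure = float(np.exp(coef)), "RaR"
    return EffectEstimate(
        outcome, contrast, "conditional", "regression", measure, point,
        n_used=len(sub), diagnostics={"family": fit.family, "nb_alpha": fit.nb_alpha},
    )


def estimate_ipw(
    table: pd.DataFrame,
    ps_result: PropensityResult,
    outcome: str,
    contrast: TreatmentContrast,
    estimand: str = "ATE",
    family: Optional[str] = None,
    ratio_mode: str = "coefficient",
    weight_cap_warn: float = 50.0,
    nb_alpha: Optional[float] = None,
) -> EffectEstimate:
    """Weighted treatment-only outcome model in the pseudo-population.

    Count outcomes report the exponentiated treatment coefficient by
    default (``ratio_mode="aggregate"`` reports the ratio of weighted
    aggregate rates instead; the two coincide for Poisson).  The binary
    outcome reports the ratio of weighted outcome means (a risk ratio, not
    an odds ratio); scores report the weighted mean difference.
    """
    sub, y, a, exposure, meta = _outcome_frame(table, outcome, contrast)
    fam = _ratio_family(meta, family)
    ws = ipw_weights(ps_result.ps.loc[sub.index], a, estimand=estimand)
    w = ws.weights.to_numpy()
    diags = {
        "max_weight": ws.max_weight,
        "effective_n": ws.effective_n,
        "estimand": estimand,
    }
    if ws.max_weight > weight_cap_warn:
        diags["extreme_weights"] = True

    a_np = a.to_numpy()
    if fam in ("negbin", "poisson"):
        if ratio_mode == "aggregate":
            re_ = np.sum(w[a_np == 1] * y[a_np == 1]) / np.sum(
                w[a_np == 1] * exposure[a_np == 1]
            )
            rr_ = np.sum(w[a_np == 0] * y[a_np == 0]) / np.sum(
                w[a_np == 0] * exposure[a_np == 0]
            )
            point = float(re_ / rr_)
        else:
            fit = fit_outcome_model(
                y, _treatment_design(a), fam, exposure=exposure, weights=w,
                nb_alpha=nb_alpha,
            )
            point = float(np.exp(fit.result.params["treat"]))
            diags["nb_alpha"] = fit.nb_alpha
        measure = "RaR"
    elif fam == "logistic":
        pe = np.sum(w[a_np == 1] * y[a_np == 1]) / np.sum(w[a_np == 1])
        pr = np.sum(w[a_np == 0] * y[a_np == 0]) / np.sum(w[a_np == 0])
        point, measure = float(pe / pr), "RiR"
    else:
        me = np.sum(w[a_np == 1] * y[a_np == 1]) / np.sum(w[a_np == 1])
        mr = np.sum(w[a_np == 0] * y[a_np == 0]) / np.sum(w[a_np == 0])
        point, measure = float(me - mr), "Delta"
    return EffectEstimate(
        outcome, contrast, estimand, "IPW", measure, point, n_used=len(sub),
        diagnostics=diags,
    )


def gcomp_estimates(
    table: pd.DataFrame,
    outcome: str,
    contrast: TreatmentContrast,
    estimands: Sequence[str] = ("ATE",),
    spec: Optional[CovariateSpec] = None,
    family: Optional[str] = None,
    convention: str = "aggregate",
    design: Optional[pd.DataFrame] = None,
    nb_alpha: Optional[float] = None,
) -> dict[str, EffectEstimate]:
    """Marginal standardisation from one outcome-model fit.

    Fits the outcome family on confounders + treatment, predicts each
    pupil's expected outcome under both arms and averages over the estimand
    population (everyone for ATE, the exposed for ATT).  Count outcomes use
    the exposure-weighted (aggregate) convention by default; a
    pupil-averaged-rate alternative is available.
    """
    sub, y, a, exposure, meta = _outcome_frame(table, outcome, contrast)
    fam = _ratio_family(meta, family)
    if design is None:
        X = build_design(sub, spec=spec, quadratic=False)
    else:
        X = design.loc[sub.index].copy()
    X.insert(1, "treat", a.astype(float))
    X = drop_collinear(X)
    fit = fit_outcome_model(y, X, fam, exposure=exposure, nb_alpha=nb_alpha)

    Xe, Xr = _counterfactual_designs(X)
    if fam == "linear":
        pred_e = _linear_predict_rate(fit, Xe)
        pred_r = _linear_predict_rate(fit, Xr)
    else:
        pred_e, pred_r = fit.predict_rate(Xe), fit.predict_rate(Xr)

    out: dict[str, EffectEstimate] = {}
    for estimand in estimands:
        pop = np.ones(len(sub), dtype=bool) if estimand == "ATE" else (a.to_numpy() == 1)
        if not pop.any():
            raise ValueError("empty estimand population")
        if fam in ("negbin", "poisson"):
            if convention == "aggregate":
                num = np.sum(exposure[pop] * pred_e[pop]) / np.sum(exposure[pop])
                den = np.sum(exposure[pop] * pred_r[pop]) / np.sum(exposure[pop])
            else:
                num, den = pred_e[pop].mean(), pred_r[pop].mean()
            point, measure = float(num / den), "RaR"
        elif fam == "logistic":
            point, measure = float(pred_e[pop].mean() / pred_r[pop].mean()), "RiR"
        else:
            point, measure = float(pred_e[pop].mean() - pred_r[pop].mean()), "Delta"
        out[estimand] = EffectEstimate(
            outcome, contrast, estimand, "gcomp", measure, point, n_used=len(sub),
            diagnostics={
                "family": fit.family, "nb_alpha": fit.nb_alpha,
                "convention": convention,
            },
        )
    return out


def estimate_gcomp(
    table: pd.DataFrame,
    outcome: str,
    contrast: TreatmentContrast,
    estimand: str = "ATE",
    **kwargs,
) -> EffectEstimate:
    """Single-estimand wrapper around :func:`gcomp_estimates`."""
    return gcomp_estimates(table, outcome, contrast, estimands=(estimand,), **kwargs)[
        estimand
    ]


def aipw_estimates(
    table: pd.DataFrame,
    ps_result: PropensityResult,
    outcome: str,
    contrast: TreatmentContrast,
    estimands: Sequence[str] = ("ATE",),
    spec: Optional[CovariateSpec] = None,
    count_family: str = "poisson",
    eps: float = 1e-3,
    use_lasso: bool = False,
    lasso_seed: Optional[int] = None,
    outcome_design: Optional[pd.DataFrame] = None,
) -> dict[str, EffectEstimate]:
    """Augmented IPW (doubly robust) counterfactual means.

    psi_a = mean_i [ 1{A_i=a}/p_a(X_i) * (Y_i - m_a(X_i)) + m_a(X_i) ] with
    Y and m on the rate scale for counts (observed count / exposure;
    predicted rate), probability scale for the binary outcome, raw scale for
    scores.  Count outcome models default to Poisson.  The ATT variant
    weights reference-arm residuals by p/(1-p), normalised — reported as an
    extension since the source layout leaves AIPW ATT blank.
    """
    sub, y, a, exposure, meta = _outcome_frame(table, outcome, contrast)
    fam = _ratio_family(meta, None)
    if fam == "negbin":
        fam = count_family
    ps = ps_result.ps.loc[sub.index].to_numpy()
    if np.any((ps < eps) | (ps > 1 - eps)):
        raise ValueError(f"propensity scores outside ({eps}, {1 - eps}): positivity")

    if outcome_design is None:
        X = build_design(sub, spec=spec, quadratic=False)
    else:
        X = outcome_design.loc[sub.index].copy()
    X.insert(1, "treat", a.astype(float))
    X = drop_collinear(X)
    if use_lasso:
        lfam = {"poisson": "poisson", "negbin": "poisson", "logistic": "logistic", "linear": "gaussian"}[fam]
        off = None if exposure is None else np.log(exposure)
        sel = lasso_select(
            X, y, family=lfam, seed=lasso_seed, forced=("const", "treat"), offset=off
        )
        X = X[sel["selected"]]
    fit = fit_outcome_model(y, X, fam, exposure=exposure)

    Xe, Xr = _counterfactual_designs(X)
    if fam == "linear":
        m1, m0 = _linear_predict_rate(fit, Xe), _linear_predict_rate(fit, Xr)
    else:
        m1, m0 = fit.predict_rate(Xe), fit.predict_rate(Xr)
    rate = y if exposure is None else y / exposure
    a_np = a.to_numpy()

    out: dict[str, EffectEstimate] = {}
    for estimand in estimands:
        if estimand == "ATE":
            psi1 = np.mean(a_np / ps * (rate - m1) + m1)
            psi0 = np.mean((1 - a_np) / (1 - ps) * (rate - m0) + m0)
        elif estimand == "ATT":
            psi1 = rate[a_np == 1].mean()
            w0 = ps[a_np == 0] / (1 - ps[a_np == 0])
            corr = np.sum(w0 * (rate[a_np == 0] - m0[a_np == 0])) / np.sum(w0)
            psi0 = m0[a_np == 1].mean() + corr
        else:
            raise ValueError(f"unknown estimand {estimand!r}")

        if fam in ("poisson", "negbin"):
            point, measure = float(psi1 / psi0), "RaR"
        elif fam == "logistic":
            point, measure = float(psi1 / psi0), "RiR"
        else:
            point, measure = float(psi1 - psi0), "Delta"
        diags = {
            "family": fit.family,
            "psi_exposed": float(psi1),
            "psi_reference": float(psi0),
            "estimand": estimand,
        }
        if estimand == "ATT":
            diags["att_extension"] = True
        if use_lasso:
            diags["lasso_selected"] = list(X.columns)
        out[estimand] = EffectEstimate(
            outcome, contrast, estimand, "AIPW", measure, point, n_used=len(sub),
            diagnostics=diags,
        )
    return out


def estimate_aipw(
    table: pd.DataFrame,
    ps_result: PropensityResult,
    outcome: str,
    contrast: TreatmentContrast,
    estimand: str = "ATE",
    **kwargs,
) -> EffectEstimate:
    """Single-estimand wrapper around :func:`aipw_estimates`."""
    return aipw_estimates(
        table, ps_result, outcome, contrast, estimands=(estimand,), **kwargs
    )[estimand]
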