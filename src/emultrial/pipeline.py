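"""End-to-end emulated-trial analysis: simulate/load -> prep -> PS gate ->
triangulated estimation -> cluster-bootstrap CIs -> report tables.

A contrast only ever leaves the pipeline through the positivity gate (with
an explicit refusal record), never through a silent crash: poor-overlap
comparisons are refused rather than extrapolated, reproducing the decision
to analyse only the well-overlapped contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig, default_config
from .design import CovariateSpec
from .estimators import (
    OUTCOMES,
    estimate_aipw,
    estimate_conditional,
    estimate_crude,
    estimate_gcomp,
    estimate_ipw,
    fit_outcome_model,
    _outcome_frame,
    _treatment_design,
)
from .prep import build_analysis_table, complete_records_filter, restrict_followup
from .propensity import TreatmentContrast, fit_ps_model, overlap_summary, positivity_check
from .simulate import generate_cohort, read_cohort, write_cohort
from .uncertainty import cluster_bootstrap, cluster_robust_se

DEFAULT_OUTCOMES = (
    "hospital",
    "medical_absence",
    "unauthorised_absence",
    "persistent",
    "ks1",
    "ks2",
)


@dataclass
class RunConfig:
    cohort_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    contrasts: Sequence[tuple[str, str]] = (("Support", "None"),)
    outcomes: Sequence[str] = DEFAULT_OUTCOMES
    estimators: Sequence[str] = ("IPW", "gcomp", "AIPW")
    estimands: Sequence[str] = ("ATE", "ATT")
    B: int = 1000
    seed: int = 0
    use_lasso: bool = False
    year2_censor: bool = False
    complete_records: bool = False
    disaggregate_hospital: bool = False
    min_per_cell: int = 5
    outdir: Optional[str] = None

    def validate(self) -> None:
        if not self.outcomes or not self.contrasts:
            raise ValueError("need at least one outcome and one contrast")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")


def disaggregate_hospital(table: pd.DataFrame) -> pd.DataFrame:
    """Expose A&E-day and admitted-day counts as standalone outcomes.

    Validates the accounting identity AE + APC - same-day overlap = total
    unplanned days for every pupil.
    """
    for col in ("hospital_days_ae", "hospital_days_apc"):
        if col not in table:
            raise ValueError("component hospital day counts absent")
    overlap = (
        table["hospital_days_ae"]
        + table["hospital_days_apc"]
        - table["hospital_days_unplanned"]
    )
    if (overlap < 0).any():
        raise ValueError("negative same-day overlap: inconsistent components")
    return table


def estimate_points(
    table: pd.DataFrame,
    contrast: TreatmentContrast,
    outcomes: Sequence[str],
    estimators: Sequence[str],
    estimands: Sequence[str],
    spec: Optional[CovariateSpec] = None,
    nb_alphas: Optional[dict] = None,
    use_lasso: bool = False,
    lasso_seed: Optional[int] = None,
) -> dict[str, float]:
    """One pass of the full causal chain; returns named point estimates.

    This is the closure the cluster bootstrap re-runs: the PS model is
    re-fitted inside each replicate so nuisance uncertainty propagates into
    the intervals.  NB dispersions may be pinned (``nb_alphas``) to the
    full-sample ML values.
    """
    from .design import build_design
    from .estimators import aipw_estimates, gcomp_estimates
    from .propensity import subset_contrast

    # one two-arm subset and one design matrix serve every estimator below
    tsub = subset_contrast(table, contrast)
    X_out = build_design(tsub, spec=spec, quadratic=False)
    X_ps = build_design(tsub, spec=spec, quadratic=True)
    ps_res = fit_ps_model(tsub, contrast, design=X_ps)
    table = tsub
    out: dict[str, float] = {}
    nb_alphas = nb_alphas or {}
    for oc in outcomes:
        alpha = nb_alphas.get(oc)
        for est in estimators:
            if est == "IPW":
                for estimand in estimands:
                    e = estimate_ipw(
                        table, ps_res, oc, contrast, estimand=estimand,
                        nb_alpha=alpha,
                    )
                    out[f"{oc}|{est}|{estimand}"] = e.point
            elif est == "gcomp":
                ests = gcomp_estimates(
                    table, oc, contrast, estimands=estimands, spec=spec,
                    nb_alpha=alpha, design=X_out,
                )
                for estimand, e in ests.items():
                    out[f"{oc}|{est}|{estimand}"] = e.point
            elif est == "AIPW":
                ests = aipw_estimates(
                    table, ps_res, oc, contrast, estimands=estimands, spec=spec,
                    use_lasso=use_lasso, lasso_seed=lasso_seed,
                    outcome_design=X_out,
                )
                for estimand, e in ests.items():
                    out[f"{oc}|{est}|{estimand}"] = e.point
            else:
                raise ValueError(f"unknown estimator {est!r}")
    return out


def profile_nb_dispersions(
    table: pd.DataFrame,
    contrast: TreatmentContrast,
    outcomes: Sequence[str],
    spec: Optional[CovariateSpec] = None,
) -> dict[str, float]:
    """Full-sample ML dispersion per count outcome.

    Bootstrap replicates reuse these values (coefficients are refit per
    replicate; the dispersion search is the expensive part of an NB fit).
    """
    alphas: dict[str, float] = {}
    for oc in outcomes:
        if OUTCOMES[oc]["family"] != "negbin":
            continue
        e = estimate_conditional(table, oc, contrast, spec=spec)
        if e.diagnostics.get("nb_alpha"):
            alphas[oc] = float(e.diagnostics["nb_alpha"])
    return alphas


def _regression_rows(table, contrast, outcomes, spec) -> list[dict]:
    """Crude and conditional rows with cluster-robust Wald CIs."""
    rows = []
    for oc in outcomes:
        for which, fn in (("crude", estimate_crude), ("conditional", estimate_conditional)):
            try:
                est = fn(table, oc, contrast) if which == "crude" else fn(
                    table, oc, contrast, spec=spec
                )
            except ValueError:
                continue
            # rebuild the fit to extract a cluster-robust CI on the
            # treatment coefficient
            sub, y, a, exposure, meta = _outcome_frame(table, oc, contrast)
            from .design import build_design, drop_collinear

            if which == "crude":
                X = _treatment_design(a)
            else:
                X = build_design(sub, spec=spec, quadratic=False)
                X.insert(1, "treat", a.astype(float))
                X = drop_collinear(X)
            fam = meta["family"]
            fit = fit_outcome_model(y, X, fam, exposure=exposure)
            try:
                se = cluster_robust_se(fit.result, sub["cluster_id"])["treat"]
            except Exception:  # noqa: BLE001
                se = np.nan
            coef = float(fit.result.params["treat"])
            lo, hi = coef - 1.96 * se, coef + 1.96 * se
            if est.measure in ("RaR", "RiR", "OR"):
                lo, hi = float(np.exp(lo)), float(np.exp(hi))
            est.ci_low, est.ci_high = lo, hi
            rows.append(est.as_row())
    return rows


def run_pipeline(run_config: RunConfig) -> dict:
    """Full emulated-trial analysis; returns a results bundle.

    Bundle keys: ``results`` (long-format estimates), ``refusals`` (contrasts
    stopped at the positivity gate), ``overlap`` (decile tables),
    ``descriptives``, ``log``.
    """
    rc = run_config
    rc.validate()
    ss = np.random.SeedSequence(rc.seed)
    s_gen, s_boot, s_lasso = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    log = {
        "version": __version__,
        "seed": rc.seed,
        "stage_seeds": {"generator": s_gen, "bootstrap": s_boot, "lasso": s_lasso},
        "B": rc.B,
    }

    if rc.cohort_csv is not None:
        cohort_df = read_cohort(rc.cohort_csv)
    else:
        gen = rc.generator or default_config()
        cohort_df = generate_cohort(gen, seed=s_gen).data
    if rc.year2_censor:
        cohort_df = restrict_followup(cohort_df, horizon_year=2)
    table = build_analysis_table(cohort_df)
    if rc.complete_records:
        table, retained = complete_records_filter(table)
        log["complete_records_retained"] = retained
    outcomes = list(rc.outcomes)
    if rc.year2_censor:
        outcomes = [o for o in outcomes if o not in ("ks2", "progress_ks2")]
    if rc.disaggregate_hospital:
        disaggregate_hospital(table)
        outcomes = outcomes + ["hospital_ae", "hospital_apc"]

    spec = CovariateSpec()
    all_rows, refusals, overlaps = [], [], {}
    for exposed, reference in rc.contrasts:
        contrast = TreatmentContrast(exposed, reference)
        ps_res = fit_ps_model(table, contrast, spec=spec)
        ov = overlap_summary(ps_res)
        flag = positivity_check(ov, min_per_cell=rc.min_per_cell)
        overlaps[str(contrast)] = ov
        if flag == "fail":
            refusals.append(
                {
                    "contrast": str(contrast),
                    "reason": "positivity failure: propensity distributions do not overlap",
                    "shared_support": ov.attrs["shared_support"],
                }
            )
            continue

        all_rows.extend(_regression_rows(table, contrast, outcomes, spec))

        nb_alphas = profile_nb_dispersions(table, contrast, outcomes, spec=spec)
        closure_kwargs = dict(
            contrast=contrast, outcomes=outcomes, estimators=rc.estimators,
            estimands=rc.estimands, spec=spec, use_lasso=rc.use_lasso,
            lasso_seed=s_lasso, nb_alphas=nb_alphas,
        )
        boot = cluster_bootstrap(
            table,
            lambda t: estimate_points(t, **closure_kwargs),
            B=rc.B,
            seed=s_boot,
        )
        for key, point in boot.point.items():
            oc, est, estimand = key.split("|")
            meta_fam = OUTCOMES[oc]["family"]
            measure = {"negbin": "RaR", "logistic": "RiR", "linear": "Delta"}[meta_fam]
            lo, hi = boot.ci(key)
            all_rows.append(
                {
                    "outcome": oc, "contrast": str(contrast), "estimand": estimand,
                    "estimator": est, "measure": measure, "point": point,
                    "ci_low": lo, "ci_high": hi,
                    "n": int((table["treatment"].isin([exposed, reference])).sum()),
                }
            )

    results = pd.DataFrame(all_rows)
    bundle = {
        "results": results,
        "refusals": refusals,
        "overlap": overlaps,
        "descriptives": describe_cohort(table),
        "log": log,
    }
    if rc.outdir:
        _write_bundle(bundle, rc.outdir)
    return bundle


def describe_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Arm-wise outcome totals and rates (the descriptive-table analogue)."""
    rows = []
    for arm, grp in table.groupby("treatment"):
        has_sess = grp["sessions_possible"] > 0
        pers = grp["persistent_flag"]
        rows.append(
            {
                "treatment": arm,
                "n": len(grp),
                "hospital_days": int(grp["hospital_days_unplanned"].sum()),
                "followup_years": float(grp["followup_years"].sum()),
                "hosp_rate_per_1000y": float(
                    grp["hospital_days_unplanned"].sum() / grp["followup_years"].sum() * 1000
                ),
                "medical_sessions": int(grp["sessions_medical"].sum()),
                "possible_sessions": int(grp["sessions_possible"].sum()),
                "medical_rate_per_1000s": float(
                    grp["sessions_medical"].sum() / grp["sessions_possible"].sum() * 1000
                ),
                "unauth_rate_per_1000s": float(
                    grp["sessions_unauthorised"].sum() / grp["sessions_possible"].sum() * 1000
                ),
                "persistent_pct": float(pers.dropna().astype(float).mean() * 100),
                "n_absence": int(has_sess.sum()),
            }
        )
    return pd.DataFrame(rows)


def render_tables(bundle: dict, decimals: int = 2) -> dict[str, str]:
    """Markdown tables, one block per outcome, estimators in fixed order."""
    results: pd.DataFrame = bundle["results"]
    order = ["regression", "IPW", "gcomp", "AIPW"]
    texts = {}
    for contrast, cgrp in (results.groupby("contrast") if len(results) else ()):
        lines = [f"## Effect estimates: {contrast}", ""]
        lines.append("| Outcome | Contrast | Estimator | Measure | Point | 95% CI |")
        lines.append("|---|---|---|---|---|---|")
        for oc, grp in cgrp.groupby("outcome", sort=False):
            grp = grp.copy()
            grp["order"] = grp["estimator"].map({e: i for i, e in enumerate(order)})
            grp = grp.sort_values(["order", "estimand"])
            for _, r in grp.iterrows():
                ci = (
                    f"{r['ci_low']:.{decimals}f}, {r['ci_high']:.{decimals}f}"
                    if np.isfinite(r["ci_low"])
                    else "-"
                )
                lines.append(
                    f"| {oc} | {r['estimand']} | {r['estimator']} | {r['measure']} "
                    f"| {r['point']:.{decimals}f} | {ci} |"
                )
        texts[contrast] = "\n".join(lines) + "\n"
    for refusal in bundle.get("refusals", []):
        texts[refusal["contrast"]] = (
            f"## {refusal['contrast']}\n\nContrast refused: {refusal['reason']}\n"
        )
    return texts


def _write_bundle(bundle: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["results"].to_csv(out / "results.csv", index=False)
    bundle["descriptives"].to_csv(out / "descriptives.csv", index=False)
    for contrast, ov in bundle["overlap"].items():
        safe = contrast.replace(" ", "_")
        ov.to_csv(out / f"overlap_{safe}.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {"log": bundle["log"], "refusals": bundle["refusals"]}, fh, indent=1,
            default=str,
        )
    for contrast, text in render_tables(bundle).items():
        safe = contrast.replace(" ", "_")
        with open(out / f"table_{safe}.md", "w") as fh:
            fh.write(text)
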