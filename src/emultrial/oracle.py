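"""Monte-Carlo potential-outcome truths for a generator configuration.

For every outcome and treatment contrast the oracle simulates *both*
potential outcomes for each Monte-Carlo pupil on shared noise (cluster
intercepts, frailties, score residuals) and reports the true marginal
effects on the reporting scale of the study:

* count outcomes - rate ratio (RaR), total potential events over total
  offset, exposed vs reference;
* persistent absence - risk ratio (RiR) of the derived >= 10 % flag;
* scores - mean difference (Delta) among pupils whose follow-up reaches the
  assessment (assessment availability is independent of assignment).

ATE averages over the whole population, ATT over pupils whose *realised*
draw from the assignment law is the exposed level.  Monte-Carlo standard
errors come from batch means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import GeneratorConfig, TREATMENT_LEVELS
from . import simulate as sim

#: analysed outcomes and their effect measures
OUTCOME_MEASURES = {
    "hospital": "RaR",
    "hospital_ae": "RaR",
    "hospital_apc": "RaR",
    "medical_absence": "RaR",
    "unauthorised_absence": "RaR",
    "persistent": "RiR",
    "ks1": "Delta",
    "ks2": "Delta",
}

PERSISTENT_THRESHOLD = 0.10


@dataclass
class OracleTruth:
    """Long-format truths: outcome x contrast x estimand with MC SEs."""

    table: pd.DataFrame
    n_mc: int
    seed: Optional[int]

    def lookup(self, outcome: str, estimand: str, exposed: str, reference: str) -> tuple[float, float]:
        t = self.table
        row = t[
            (t["outcome"] == outcome)
            & (t["estimand"] == estimand)
            & (t["exposed"] == exposed)
            & (t["reference"] == reference)
        ]
        if len(row) != 1:
            raise KeyError(f"no unique truth for {outcome}/{estimand}/{exposed} vs {reference}")
        return float(row["truth"].iloc[0]), float(row["mc_se"].iloc[0])


def _arm_outcomes(config, design, level, followup, noise, rng, year_index):
    """Realised outcomes for the whole MC population assigned to ``level``."""
    treatment = np.full(len(design), level, dtype=object)
    return sim.simulate_outcomes(
        design, treatment, config, followup, noise, rng, year_index=year_index
    )


def _measures_for_arm(out: pd.DataFrame, mask: np.ndarray) -> dict[str, tuple[float, float]]:
    """(numerator, denominator) totals / means per outcome within ``mask``."""
    o = out[mask]
    res: dict[str, tuple[float, float]] = {}
    fu = o["followup_years"].sum()
    res["hospital"] = (o["hospital_days_unplanned"].sum(), fu)
    res["hospital_ae"] = (o["hospital_days_ae"].sum(), fu)
    res["hospital_apc"] = (o["hospital_days_apc"].sum(), fu)
    sess = o["sessions_possible"].sum()
    res["medical_absence"] = (o["sessions_medical"].sum(), sess)
    res["unauthorised_absence"] = (o["sessions_unauthorised"].sum(), sess)
    has_sess = o["sessions_possible"] > 0
    missed = (
        o["sessions_medical"] + o["sessions_unauthorised"] + o["sessions_other"]
    )
    persistent = (missed[has_sess] / o.loc[has_sess, "sessions_possible"]) >= PERSISTENT_THRESHOLD
    res["persistent"] = (persistent.sum(), int(has_sess.sum()))
    for name in ("ks1", "ks2"):
        col = o.get(f"{name}_raw")
        if col is not None:
            res[name] = (col.sum(skipna=True), int(col.notna().sum()))
    return res


def true_marginal_effects(
    config: GeneratorConfig,
    n_mc: int = 200_000,
    seed: Optional[int] = None,
    contrasts: Sequence[tuple[str, str]] = (("Support", "None"),),
    n_batches: int = 20,
) -> OracleTruth:
    """Simulate potential outcomes under each arm and average.

    Scores are compared on the latent z scale (year-marking drift cancels
    between arms only after standardisation; the latent scale is the
    estimand the analysis targets after per-year standardisation).
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    r_cov, r_trt, r_fu, r_noise, *r_arms = (
        np.random.default_rng(s) for s in ss.spawn(4 + len(TREATMENT_LEVELS))
    )

    cov = sim.draw_covariates(n_mc, config.n_clusters, r_cov)
    design = sim.generator_design(cov)
    realised = sim.assign_treatment(design, config.ps_coefficients, r_trt)
    year_index = cov["academic_year"].to_numpy() - 2008
    followup = sim.draw_followup(year_index, config, r_fu)
    noise = sim.draw_shared_noise(config, n_mc, cov["cluster_id"].to_numpy(), r_noise)

    levels_needed = sorted({lev for c in contrasts for lev in c})
    arm_out = {}
    for lev, rng_a in zip(TREATMENT_LEVELS, r_arms):
        if lev in levels_needed:
            arm_out[lev] = _arm_outcomes(
                config, design, lev, followup, noise, rng_a, year_index
            )
            # latent z scores for Delta truths
            for name in ("ks1", "ks2"):
                if f"{name}_raw" in arm_out[lev]:
                    shift, scale = sim._year_marking(year_index, name)
                    arm_out[lev][f"{name}_z"] = (
                        arm_out[lev][f"{name}_raw"] - shift
                    ) / scale

    batch = np.arange(n_mc) % n_batches
    rows = []
    for exposed, reference in contrasts:
        for estimand in ("ATE", "ATT"):
            mask = np.ones(n_mc, dtype=bool) if estimand == "ATE" else (realised == exposed)
            ests, per_batch = {}, {}
            for b in range(-1, n_batches):
                m = mask if b < 0 else (mask & (batch == b))
                me = _measures_for_arm(arm_out[exposed], m)
                mr = _measures_for_arm(arm_out[reference], m)
                for name, measure in OUTCOME_MEASURES.items():
                    if measure == "Delta":
                        ne, de = arm_out[exposed].loc[m, f"{name}_z"], None
                        nr = arm_out[reference].loc[m, f"{name}_z"]
                        val = ne.mean(skipna=True) - nr.mean(skipna=True)
                    else:
                        (ae_, be_), (ar_, br_) = me[name], mr[name]
                        val = (ae_ / be_) / (ar_ / br_) if br_ > 0 and be_ > 0 and ar_ > 0 else np.nan
                    if b < 0:
                        ests[name] = val
                    else:
                        per_batch.setdefault(name, []).append(val)
            for name, measure in OUTCOME_MEASURES.items():
                vals = np.asarray(per_batch[name], dtype=float)
                mc_se = np.nanstd(vals, ddof=1) / np.sqrt(np.sum(np.isfinite(vals)))
                rows.append(
                    {
                        "outcome": name,
                        "measure": measure,
                        "exposed": exposed,
                        "reference": reference,
                        "estimand": estimand,
                        "truth": ests[name],
                        "mc_se": mc_se,
                    }
                )
    return OracleTruth(table=pd.DataFrame(rows), n_mc=n_mc, seed=seed)
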