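"""Effect estimators: weights, model fits, published 2x2 checks, and the
saturated-model equivalence with exact nonparametric standardisation."""

import math

import numpy as np
import pandas as pd
import pytest

import emultrial as et
from emultrial.estimators import (
    aipw_estimates,
    fit_outcome_model,
    gcomp_estimates,
    ipw_weights,
)
from emultrial.propensity import TreatmentContrast

CON = TreatmentContrast("Support", "None")


class TestWeights:
    def test_ate_weights(self):
        ws = ipw_weights([0.5, 0.25], [1, 1], "ATE")
        assert np.allclose(ws.weights, [2.0, 4.0])
        ws = ipw_weights([0.5], [0], "ATE")
        assert np.allclose(ws.weights, [2.0])

    def test_att_weights(self):
        ws = ipw_weights([0.5, 0.5], [1, 0], "ATT")
        assert np.allclose(ws.weights, [1.0, 1.0])  # exposed 1; ref 0.5/0.5

    def test_degenerate_ps_rejected(self):
        with pytest.raises(ValueError, match="positivity"):
            ipw_weights([0.0, 0.5], [1, 0], "ATE")


class TestOutcomeModels:
    def test_intercept_only_poisson_rate_identity(self, rng):
        y = rng.poisson(2.0, size=500).astype(float)
        expo = rng.uniform(0.5, 2.0, size=500)
        X = pd.DataFrame({"const": np.ones(500)})
        fit = fit_outcome_model(y, X, "poisson", exposure=expo)
        assert math.exp(fit.result.params["const"]) == pytest.approx(
            y.sum() / expo.sum(), rel=1e-8
        )

    def test_published_persistent_absence_two_by_two_odds_ratio(self):
        # exposed 295/2007, reference 314/4347
        y = np.concatenate(
            [np.ones(295), np.zeros(2007 - 295), np.ones(314), np.zeros(4347 - 314)]
        )
        a = np.concatenate([np.ones(2007), np.zeros(4347)])
        X = pd.DataFrame({"const": 1.0, "treat": a})
        fit = fit_outcome_model(y, X, "logistic")
        assert math.exp(fit.result.params["treat"]) == pytest.approx(2.21, abs=0.005)

    def test_published_hospitalisation_aggregate_rate_ratio(self):
        y = np.array([3608.0, 5634.0])
        expo = np.array([8276.6, 16931.2])
        X = pd.DataFrame({"const": [1.0, 1.0], "treat": [1.0, 0.0]})
        fit = fit_outcome_model(y, X, "poisson", exposure=expo)
        assert math.exp(fit.result.params["treat"]) == pytest.approx(1.31, abs=0.005)

    def test_nb_profile_recovers_dispersion(self, rng):
        n = 4000
        g = rng.gamma(2.0, 0.5, size=n)  # alpha = 0.5
        y = rng.poisson(3.0 * g).astype(float)
        X = pd.DataFrame({"const": np.ones(n)})
        fit = fit_outcome_model(y, X, "negbin", exposure=np.ones(n))
        assert fit.family == "negbin"
        assert fit.nb_alpha == pytest.approx(0.5, abs=0.1)

    def test_equidispersed_counts_fall_back_to_poisson(self, rng):
        y = rng.poisson(3.0, size=3000).astype(float)
        X = pd.DataFrame({"const": np.ones(3000)})
        with pytest.warns(UserWarning, match="Poisson"):
            fit = fit_outcome_model(y, X, "negbin", exposure=np.ones(3000))
        assert fit.family == "poisson"

    def test_zero_variance_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(5)})
        with pytest.raises(ValueError, match="zero-variance"):
            fit_outcome_model(np.ones(5), X, "linear")


def _discrete_fixture():
    """40-pupil fixture, one binary confounder, heterogeneous rate ratios.

    Cell rates: (l=0) 0.5 vs 1.0 per year; (l=1) 3.0 vs 5.0 per year —
    ratios 2.0 and 1.667, so standardisation genuinely mixes strata.
    Exposure depends on the stratum only (2y in l=0, 1y in l=1).
    """
    # (stratum l, arm a): n pupils, events per pupil, exposure per pupil
    layout = {
        (0, 0): (12, 1, 2.0),
        (0, 1): (4, 2, 2.0),
        (1, 0): (6, 3, 1.0),
        (1, 1): (18, 5, 1.0),
    }
    rows = []
    pid = 0
    for (l, a), (n, y, expo) in layout.items():
        for _ in range(n):
            rows.append(
                {
                    "pupil_id": pid,
                    "treatment": "Support" if a else "None",
                    "l": float(l),
                    "hospital_days_unplanned": y,
                    "followup_years": expo,
                    "cluster_id": pid % 4,
                }
            )
            pid += 1
    return pd.DataFrame(rows), layout


def exact_standardisation(layout, estimand="ATE", convention="pupil"):
    """Enumeration oracle: sum_l weight(l) * rate(a, l), ratio of arms."""
    num = den = 0.0
    for l in (0, 1):
        n_l = layout[(l, 0)][0] + layout[(l, 1)][0]
        if estimand == "ATT":
            n_l = layout[(l, 1)][0]
        expo_l = layout[(l, 0)][2]
        rate = {a: layout[(l, a)][1] / layout[(l, a)][2] for a in (0, 1)}
        w = n_l * expo_l if convention == "aggregate" else n_l
        num += w * rate[1]
        den += w * rate[0]
    return num / den


def _saturated_design(table):
    return pd.DataFrame(
        {"const": 1.0, "l": table["l"], "treat_x_l": 0.0}, index=table.index
    )


class TestOracleEquivalence:
    def test_saturated_gcomp_matches_enumeration(self):
        table, layout = _discrete_fixture()
        for estimand in ("ATE", "ATT"):
            for convention in ("pupil", "aggregate"):
                truth = exact_standardisation(layout, estimand, convention)
                design = _saturated_design(table)
                design["treat_x_l"] = (
                    (table["treatment"] == "Support").astype(float) * table["l"]
                )
                g = gcomp_estimates(
                    table, "hospital", CON, estimands=(estimand,),
                    family="poisson", design=design, convention=convention,
                )[estimand]
                assert g.point == pytest.approx(truth, abs=1e-10)

    def test_saturated_ipw_matches_enumeration(self):
        table, layout = _discrete_fixture()
        ps_design = pd.DataFrame(
            {"const": 1.0, "l": table["l"]}, index=table.index
        )
        ps = et.fit_ps_model(table, CON, design=ps_design)
        # aggregate IPW ratio = exposure-weighted exact standardisation
        truth = exact_standardisation(layout, "ATE", "aggregate")
        ipw = et.estimate_ipw(
            table, ps, "hospital", CON, family="poisson", ratio_mode="aggregate"
        )
        assert ipw.point == pytest.approx(truth, abs=1e-10)
        # Horvitz-Thompson mean of pupil rates = pupil-average standardisation
        truth_p = exact_standardisation(layout, "ATE", "pupil")
        w = ipw_weights(
            ps.ps, (table["treatment"] == "Support").astype(int), "ATE"
        ).weights.to_numpy()
        rate = (table["hospital_days_unplanned"] / table["followup_years"]).to_numpy()
        a = (table["treatment"] == "Support").to_numpy()
        ht = (np.sum(w[a] * rate[a]) / np.sum(w[a])) / (
            np.sum(w[~a] * rate[~a]) / np.sum(w[~a])
        )
        assert ht == pytest.approx(truth_p, abs=1e-10)

    def test_saturated_aipw_matches_enumeration(self):
        table, layout = _discrete_fixture()
        ps_design = pd.DataFrame({"const": 1.0, "l": table["l"]}, index=table.index)
        ps = et.fit_ps_model(table, CON, design=ps_design)
        design = _saturated_design(table)
        design["treat_x_l"] = (
            (table["treatment"] == "Support").astype(float) * table["l"]
        )
        truth_p = exact_standardisation(layout, "ATE", "pupil")
        a = aipw_estimates(
            table, ps, "hospital", CON, estimands=("ATE",), outcome_design=design
        )["ATE"]
        assert a.point == pytest.approx(truth_p, abs=1e-10)


class TestCrudeAndConditional:
    def test_identical_arms_give_null(self, rng):
        n = 2000
        t = pd.DataFrame(
            {
                "treatment": np.where(rng.random(n) < 0.4, "Support", "None"),
                "ks1_z": rng.normal(size=n),
                "cluster_id": rng.integers(0, 20, n),
            }
        )
        e = et.estimate_crude(t, "ks1", CON)
        assert abs(e.point) < 0.1

    def test_conditional_close_to_crude_without_confounding(self, reduced_table):
        cfg_free = et.reduced_config(n_pupils=8000, hospital_effect=math.log(1.3))
        cfg_free.ps_coefficients = {"Support": {"const": -0.6}, "EHCP": {"const": -4.0}}
        t = et.build_analysis_table(et.generate_cohort(cfg_free, seed=44).data)
        crude = et.estimate_crude(t, "hospital_ae", CON, family="poisson")
        cond = et.estimate_conditional(t, "hospital_ae", CON, family="poisson")
        # rate ratios are collapsible under treatment-covariate independence
        assert cond.point == pytest.approx(crude.point, rel=0.05)
        assert crude.point == pytest.approx(1.3, rel=0.08)


class TestIPWProperties:
    def test_constant_ps_reduces_to_crude(self, reduced_table):
        t = reduced_table
        ps = et.fit_ps_model(
            t, CON, design=pd.DataFrame({"const": np.ones(len(t))}, index=t.index)
        )
        ipw = et.estimate_ipw(t, ps, "ks1", CON)
        crude = et.estimate_crude(t, "ks1", CON)
        assert ipw.point == pytest.approx(crude.point, abs=1e-6)

    def test_delta_invariant_to_score_shift(self, reduced_table):
        t = reduced_table.copy()
        ps = et.fit_ps_model(t, CON)
        base = et.estimate_ipw(t, ps, "ks1", CON).point
        t["ks1_z"] = t["ks1_z"] + 7.0
        shifted = et.estimate_ipw(t, ps, "ks1", CON).point
        assert shifted == pytest.approx(base, abs=1e-9)


class TestAIPWProperties:
    def test_no_confounding_matches_crude(self):
        cfg = et.reduced_config(n_pupils=8000, hospital_effect=math.log(1.25))
        cfg.ps_coefficients = {"Support": {"const": -0.6}, "EHCP": {"const": -4.0}}
        t = et.build_analysis_table(et.generate_cohort(cfg, seed=45).data)
        ps = et.fit_ps_model(t, CON)
        a = et.estimate_aipw(t, ps, "hospital_ae", CON)
        crude = et.estimate_crude(t, "hospital_ae", CON, family="poisson")
        assert a.point == pytest.approx(crude.point, rel=0.05)

    def test_extreme_ps_rejected(self, reduced_table):
        ps = et.fit_ps_model(reduced_table, CON)
        ps.ps.iloc[0] = 1e-6
        with pytest.raises(ValueError, match="positivity"):
            et.estimate_aipw(reduced_table, ps, "ks1", CON)

    def test_att_flagged_as_extension(self, reduced_table):
        ps = et.fit_ps_model(reduced_table, CON)
        e = et.estimate_aipw(reduced_table, ps, "ks1", CON, estimand="ATT")
        assert e.diagnostics["att_extension"] is True


class TestNullPreservation:
    def test_all_estimators_agree_under_randomised_treatment(self):
        cfg = et.reduced_config(n_pupils=10_000, hospital_effect=0.0)
        cfg.ps_coefficients = {"Support": {"const": -0.6}, "EHCP": {"const": -4.0}}
        t = et.build_analysis_table(et.generate_cohort(cfg, seed=46).data)
        ps = et.fit_ps_model(t, CON)
        ests = [
            et.estimate_crude(t, "hospital_ae", CON, family="poisson").point,
            et.estimate_ipw(t, ps, "hospital_ae", CON).point,
            et.estimate_gcomp(t, "hospital_ae", CON, family="poisson").point,
            et.estimate_aipw(t, ps, "hospital_ae", CON).point,
        ]
        assert max(ests) - min(ests) < 0.05
        for e in ests:
            assert e == pytest.approx(1.0, abs=0.08)
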