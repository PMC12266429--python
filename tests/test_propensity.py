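"""Propensity models: fits, overlap diagnostics, positivity gate, lasso."""

import numpy as np
import pandas as pd
import pytest

import emultrial as et
from emultrial.design import build_design
from emultrial.propensity import TreatmentContrast, lasso_select, subset_contrast

CON = TreatmentContrast("Support", "None")


def _const_design(table):
    return pd.DataFrame({"const": np.ones(len(table))}, index=table.index)


class TestFit:
    def test_intercept_only_gives_exposed_fraction(self):
        # arm sizes of the analysed two-arm cohort: 2009 exposed, 4350 reference
        t = pd.DataFrame(
            {"treatment": ["Support"] * 2009 + ["None"] * 4350}
        )
        res = et.fit_ps_model(t, CON, design=_const_design(t))
        assert np.allclose(res.ps, 2009 / 6359, atol=1e-8)
        assert res.ps.iloc[0] == pytest.approx(0.3159, abs=2e-4)

    def test_saturated_binary_covariate_matches_stratum_fractions(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 4000)
        p = np.where(x == 1, 0.6, 0.2)
        t = pd.DataFrame(
            {
                "treatment": np.where(rng.random(4000) < p, "Support", "None"),
                "x": x.astype(float),
            }
        )
        X = pd.DataFrame({"const": 1.0, "x": t["x"]})
        res = et.fit_ps_model(t, CON, design=X)
        for lev in (0, 1):
            stratum = t["x"] == lev
            emp = (t.loc[stratum, "treatment"] == "Support").mean()
            assert np.allclose(res.ps[stratum], emp, atol=1e-6)

    def test_mean_fitted_ps_equals_exposed_fraction(self, default_table):
        res = et.fit_ps_model(default_table, CON)
        sub = subset_contrast(default_table, CON)
        assert res.ps.mean() == pytest.approx(
            (sub["treatment"] == "Support").mean(), abs=1e-6
        )

    def test_recovers_generating_propensity(self):
        cohort = et.generate_cohort(et.default_config(n_pupils=20_000), seed=31)
        table = et.build_analysis_table(cohort.data)
        res = et.fit_ps_model(table, CON)
        pot = cohort.potential.loc[res.ps.index]
        true_ps = pot["p_Support"] / (pot["p_Support"] + pot["p_None"])
        assert np.corrcoef(res.ps, true_ps)[0, 1] > 0.95

    def test_separation_names_offender(self):
        t = pd.DataFrame(
            {
                "treatment": ["Support"] * 50 + ["None"] * 50,
                "leak": [1.0] * 50 + [0.0] * 50,
            }
        )
        X = pd.DataFrame({"const": 1.0, "leak": t["leak"]})
        with pytest.raises(et.SeparationError, match="leak"):
            et.fit_ps_model(t, CON, design=X)


class TestOverlap:
    def test_identical_distributions_populate_all_deciles(self):
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.normal(size=n)
        lp = 2.2 * x
        p = 1 / (1 + np.exp(-lp))
        t = pd.DataFrame(
            {
                "treatment": np.where(rng.random(n) < p, "Support", "None"),
                "x": x,
            }
        )
        X = pd.DataFrame({"const": 1.0, "x": t["x"]})
        res = et.fit_ps_model(t, CON, design=X)
        ov = et.overlap_summary(res)
        assert (ov[["n_reference", "n_exposed"]].sum(axis=1) > 0).all()
        assert et.positivity_check(ov) in ("pass", "warn")

    def test_support_vs_none_passes_default_config(self, default_table):
        res = et.fit_ps_model(default_table, CON)
        assert et.positivity_check(et.overlap_summary(res)) == "pass"

    def test_ehcp_contrast_fails_positivity(self, default_table):
        con = TreatmentContrast("EHCP", "None")
        res = et.fit_ps_model(default_table, con)
        ov = et.overlap_summary(res)
        # reference-arm mass concentrated at near-zero PS with no exposed
        assert et.positivity_check(ov) == "fail"
        assert ov.attrs["ps_min"]["reference"] < 0.05

    def test_single_empty_cross_arm_decile_fails(self):
        ov = pd.DataFrame(
            {
                "bin": [f"b{i}" for i in range(10)],
                "n_reference": [50] * 9 + [50],
                "n_exposed": [50] * 9 + [0],
            }
        )
        assert et.positivity_check(ov) == "fail"

    def test_sparse_low_mass_decile_warns(self):
        # 4 % of the reference arm sits where the exposed arm holds < 0.2 %
        ov = pd.DataFrame(
            {
                "bin": [f"b{i}" for i in range(10)],
                "n_reference": [107] * 9 + [40],
                "n_exposed": [1000] * 9 + [1],
            }
        )
        assert et.positivity_check(ov) == "warn"

    def test_heavy_unsupported_mass_fails(self):
        # most reference pupils live where the exposed arm is absent
        ov = pd.DataFrame(
            {
                "bin": [f"b{i}" for i in range(10)],
                "n_reference": [900] + [10] * 9,
                "n_exposed": [0] + [25] * 9,
            }
        )
        assert et.positivity_check(ov) == "fail"

    def test_gate_stable_in_sample_size(self):
        # shrinking both arms tenfold must not flip a clear pass to fail
        base = {"n_reference": [880, 1174, 887, 584, 402, 228, 118, 71, 21, 8],
                "n_exposed": [48, 209, 310, 318, 306, 285, 229, 162, 104, 24]}
        big = pd.DataFrame({"bin": [f"b{i}" for i in range(10)], **base})
        small = pd.DataFrame(
            {
                "bin": [f"b{i}" for i in range(10)],
                "n_reference": [max(1, n // 10) for n in base["n_reference"]],
                "n_exposed": [max(1, n // 10) for n in base["n_exposed"]],
            }
        )
        assert et.positivity_check(big) in ("pass", "warn")
        assert et.positivity_check(small) in ("pass", "warn")


class TestIPWBalance:
    def test_weighting_balances_modelled_covariates(self):
        table = et.build_analysis_table(
            et.generate_cohort(et.default_config(n_pupils=20_000), seed=32).data
        )
        res = et.fit_ps_model(table, CON)
        sub = subset_contrast(table, CON)
        X = build_design(sub, quadratic=False).drop(columns="const")
        a = (sub["treatment"] == "Support").to_numpy()
        w = et.ipw_weights(res.ps, a.astype(int), "ATE").weights.to_numpy()
        smds = []
        for col in X.columns:
            v = X[col].to_numpy(dtype=float)
            m1 = np.sum(w[a] * v[a]) / np.sum(w[a])
            m0 = np.sum(w[~a] * v[~a]) / np.sum(w[~a])
            pooled = np.sqrt((v[a].var() + v[~a].var()) / 2)
            if pooled > 0:
                smds.append(abs(m1 - m0) / pooled)
        assert max(smds) < 0.05


class TestLasso:
    def test_signal_covariates_selected_noise_mostly_dropped(self):
        rng = np.random.default_rng(5)
        n, true_k, noise_k = 4000, 3, 10
        X = pd.DataFrame(
            rng.normal(size=(n, true_k + noise_k)),
            columns=[f"s{i}" for i in range(true_k)]
            + [f"n{i}" for i in range(noise_k)],
        )
        X.insert(0, "const", 1.0)
        hits = {f"s{i}": 0 for i in range(true_k)}
        false_hits = 0
        seeds = range(5)
        for s in seeds:
            lp = X["s0"] * 0.8 + X["s1"] * 0.6 - X["s2"] * 0.7
            y = (np.random.default_rng(100 + s).random(n) < 1 / (1 + np.exp(-lp))).astype(float)
            sel = lasso_select(X, y, family="logistic", n_folds=5, seed=s)["selected"]
            for k in hits:
                hits[k] += k in sel
            false_hits += len([c for c in sel if c.startswith("n")])
        for k, h in hits.items():
            assert h >= 4, f"signal covariate {k} selected only {h}/5 times"
        assert false_hits <= 5 * noise_k * 0.5

    def test_pure_noise_falls_back_to_forced_terms(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        X.insert(0, "const", 1.0)
        y = (rng.random(500) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="no covariates"):
            sel = lasso_select(X, y, family="logistic", n_folds=4, seed=0)["selected"]
        assert sel == ["const"]
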