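"""Generator: assignment law, outcome families, follow-up, missingness."""

import math

import numpy as np
import pandas as pd
import pytest

import emultrial as et
from emultrial import simulate as sim
from emultrial.config import GeneratorConfig, MissingnessSpec, OutcomeSpec


def _intercept_only_config(n=20_000, sup=math.log(0.5), ehcp=math.log(0.1)):
    cfg = et.default_config(n_pupils=n)
    cfg.ps_coefficients = {"Support": {"const": sup}, "EHCP": {"const": ehcp}}
    return cfg


class TestAssignment:
    def test_zero_coefficients_give_uniform_probabilities(self, default_cohort):
        d = sim.generator_design(default_cohort.data.head(50))
        p = sim.treatment_probabilities(d, {})
        assert np.allclose(p.to_numpy(), 1 / 3)

    def test_softmax_identity_for_pure_intercepts(self, default_cohort):
        d = sim.generator_design(default_cohort.data.head(10))
        p = sim.treatment_probabilities(
            d, {"Support": {"const": math.log(0.5)}, "EHCP": {"const": math.log(0.1)}}
        )
        expect = np.array([1.0, 0.5, 0.1]) / 1.6
        assert np.allclose(p.to_numpy(), expect)

    def test_covariate_free_prevalences_match_intercepts(self):
        cfg = _intercept_only_config()
        cohort = et.generate_cohort(cfg, seed=7)
        shares = cohort.data["treatment"].value_counts(normalize=True)
        expect = {"None": 1 / 1.6, "Support": 0.5 / 1.6, "EHCP": 0.1 / 1.6}
        for lev, p in expect.items():
            se = math.sqrt(p * (1 - p) / cfg.n_pupils)
            assert abs(shares[lev] - p) < 3 * se

    def test_fsm_gradient_raises_support_share(self):
        cfg = et.default_config(n_pupils=10_000)
        d = et.generate_cohort(cfg, seed=8).data
        by_fsm = d.groupby("fsm")["treatment"].apply(
            lambda s: (s == "Support").mean()
        )
        assert by_fsm[1] > by_fsm[0]

    def test_default_arm_shares_match_study_margins(self, default_cohort):
        shares = default_cohort.data["treatment"].value_counts(normalize=True)
        for lev, p in (("None", 0.659), ("Support", 0.304), ("EHCP", 0.037)):
            se = math.sqrt(p * (1 - p) / len(default_cohort.data))
            assert abs(shares[lev] - p) < 4 * se

    def test_nonfinite_linear_predictor_raises(self, default_cohort):
        d = sim.generator_design(default_cohort.data.head(5))
        with pytest.raises(ValueError, match="unknown design feature"):
            sim.treatment_probabilities(d, {"Support": {"no_such": 1.0}})


class TestOutcomes:
    def test_record_invariants(self, default_cohort):
        d = default_cohort.data
        assert (d["sessions_medical"] + d["sessions_unauthorised"] <= d["sessions_possible"]).all()
        assert (
            d["hospital_days_unplanned"]
            <= d["hospital_days_ae"] + d["hospital_days_apc"]
        ).all()
        assert (d["hospital_days_unplanned"] <= d["followup_days"]).all()

    def test_ks2_absent_before_year6(self, default_cohort):
        d = default_cohort.data
        reached_y6 = d["fu_y6"] > 0
        assert d.loc[~reached_y6, "ks2_raw"].isna().all()
        assert d.loc[reached_y6, "ks2_raw"].notna().all()
        # late academic cohorts cannot reach the final assessment
        assert d.loc[d["academic_year"] >= 2014, "ks2_raw"].isna().all()

    def test_small_dispersion_approaches_poisson(self):
        cfg = et.default_config(n_pupils=50_000)
        spec = cfg.outcome_specs["hospital_ae"]
        spec.dispersion = 1e-4
        spec.cluster_sd = 0.0
        spec.coef = {"const": 0.0}
        d = et.generate_cohort(cfg, seed=9).data
        y, t = d["hospital_days_ae"], d["followup_years"]
        # Poisson totals with heterogeneous offsets: Var(Y) = E[Y]
        ratio = ((y - t * (y.sum() / t.sum())) ** 2).mean() / y.mean()
        assert abs(ratio - 1) < 0.05

    def test_zero_linear_predictor_gives_unit_rate(self):
        cfg = et.default_config(n_pupils=30_000)
        spec = cfg.outcome_specs["hospital_ae"]
        spec.coef = {"const": 0.0}
        spec.cluster_sd = 0.0
        spec.dispersion = 0.5
        d = et.generate_cohort(cfg, seed=10).data
        rate = d["hospital_days_ae"].sum() / d["followup_years"].sum()
        assert abs(rate - 1.0) < 0.02

    def test_null_treatment_effect_gives_unit_rate_ratio(self):
        cfg = et.default_config(n_pupils=40_000, null_effects=True)
        cfg.ps_coefficients = {"Support": {"const": 0.0}, "EHCP": {"const": -20.0}}
        d = et.generate_cohort(cfg, seed=11).data
        r = d.groupby("treatment").apply(
            lambda g: g["hospital_days_unplanned"].sum() / g["followup_years"].sum(),
            include_groups=False,
        )
        assert abs(r["Support"] / r["None"] - 1.0) < 0.05

    def test_validation_rejects_bad_family_and_dimensions(self):
        with pytest.raises(ValueError, match="family"):
            OutcomeSpec("x", "weibull", {}, {}).validate()
        cfg = et.default_config(n_pupils=300, n_clusters=30)
        cfg.outcome_specs["hospital_ae"].coef["not_a_feature"] = 1.0
        with pytest.raises(ValueError, match="unknown design feature"):
            et.generate_cohort(cfg, seed=1)
        with pytest.raises(ValueError, match="n_clusters"):
            GeneratorConfig(n_pupils=10, n_clusters=20).validate()


class TestMissingness:
    def test_zero_rate_masks_nothing(self, default_cohort, rng):
        base = default_cohort.data.copy()
        before = base["eyfsp_z"].isna().sum()
        out = sim.impose_missingness(base, {"eyfsp_z": MissingnessSpec(rate=0.0)}, rng)
        assert out["miss_eyfsp_z"].sum() == 0
        assert out["eyfsp_z"].isna().sum() == before

    def test_constant_rate_hits_marginal_fraction(self, rng):
        cfg = et.default_config(n_pupils=10_000)
        cfg.missingness = {"birthweight": MissingnessSpec(rate=0.2)}
        d = et.generate_cohort(cfg, seed=12).data
        p = d["miss_birthweight"].mean()
        assert abs(p - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 10_000)

    def test_default_unknowns_concentrate_in_birth_characteristics(self, default_cohort):
        d = default_cohort.data
        assert d["miss_gest_age"].mean() > 0.15
        assert d["miss_birthweight"].mean() > 0.10
        assert d["miss_eyfsp_z"].mean() < 0.05

    def test_unknown_covariate_rejected(self, default_cohort, rng):
        with pytest.raises(ValueError, match="unknown covariate"):
            sim.impose_missingness(
                default_cohort.data.copy(), {"shoe_size": MissingnessSpec(rate=0.1)}, rng
            )


class TestDeterminismAndIO:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = et.default_config(n_pupils=500)
        for i in (1, 2):
            et.write_cohort(et.generate_cohort(cfg, seed=42), tmp_path / f"c{i}.csv")
        assert (tmp_path / "c1.csv").read_bytes() == (tmp_path / "c2.csv").read_bytes()

    def test_yaml_config_roundtrip(self, tmp_path):
        from emultrial.config import GeneratorConfig

        cfg = et.default_config(n_pupils=400, n_clusters=20)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = GeneratorConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.to_dict() == cfg.to_dict()
        d1 = et.generate_cohort(cfg, seed=3).data
        d2 = et.generate_cohort(back, seed=3).data
        assert d1.equals(d2)

    def test_csv_roundtrip_preserves_none_level(self, tmp_path, default_cohort):
        path = tmp_path / "c.csv"
        et.write_cohort(default_cohort, path, sidecar_path=tmp_path / "c.json")
        back = et.read_cohort(path)
        assert set(back["treatment"].unique()) == {"None", "Support", "EHCP"}
        assert len(back) == len(default_cohort.data)


class TestGeneratorPositivity:
    def test_support_ps_strictly_interior(self, default_cohort):
        pot = default_cohort.potential
        cond = pot["p_Support"] / (pot["p_Support"] + pot["p_None"])
        assert cond.min() > 0.0 and cond.max() < 1.0
        assert cond.min() > 1e-4 and cond.max() < 1 - 1e-4

    def test_ehcp_law_produces_near_zero_overlap(self, default_cohort):
        pot = default_cohort.potential
        cond = pot["p_EHCP"] / (pot["p_EHCP"] + pot["p_None"])
        # the bulk of the cohort has essentially no chance of the intensive plan
        assert (cond < 0.05).mean() > 0.5
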