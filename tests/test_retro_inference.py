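"""Retrospective-likelihood fits: oracle agreement, tests, sensitivity rules."""

import numpy as np
import pytest

from carriermod import (
    EffectSpec,
    IncidenceCurve,
    SimConfig,
    default_curves,
    exclude_prevalent,
    fit,
    retro_loglik,
    simulate_cohort,
    test_age_interaction as age_interaction_test,
    test_group_difference as group_difference_test,
    test_heterogeneity as heterogeneity_test,
)
from carriermod.hazard_core import AGE_MIN

from conftest import N_AGES, make_record, toy_cohort
from oracles import grid_mle_single, oracle_loglik_single

TOY_HAZ = [0.15, 0.20, 0.18]


def toy_curve_padded():
    h = np.zeros(N_AGES)
    h[:3] = TOY_HAZ
    return IncidenceCurve("breast", "BRCA1", h)


class TestRetroLoglik:
    def test_no_followup_carries_no_phenotype_information(self):
        # everyone censored immediately: likelihood reduces to the HWE prior
        recs = [make_record(i, age_last_obs=AGE_MIN,
                            genotypes={"SNP1": g}) for i, g in
                enumerate([0, 0, 1, 1, 2])]
        curve = toy_curve_padded()
        q = 0.3
        expect = (2 * np.log((1 - q) ** 2) + 2 * np.log(2 * q * (1 - q))
                  + np.log(q**2))
        for beta in (-0.7, 0.0, 1.2):
            got = retro_loglik(recs, EffectSpec(), beta, q, curve, "SNP1")
            assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_beta_reduces_to_genotype_prior(self):
        recs = toy_cohort(n=10, seed=5)
        curve = toy_curve_padded()
        q = 0.4
        counts = [sum(r.genotypes["SNP1"] == g for r in recs)
                  for g in (0, 1, 2)]
        p = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        expect = sum(c * np.log(pg) for c, pg in zip(counts, p) if c)
        got = retro_loglik(recs, EffectSpec(), 0.0, q, curve, "SNP1")
        assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("beta,q", [(0.5, 0.4), (-0.8, 0.15), (1.3, 0.6)])
    def test_matches_enumeration_oracle(self, beta, q):
        recs = toy_cohort(n=10, seed=5)
        got = retro_loglik(recs, EffectSpec(), beta, q, toy_curve_padded(),
                           "SNP1")
        want = oracle_loglik_single(recs, "SNP1", beta, q, TOY_HAZ + [0.0])
        assert got == pytest.approx(want, abs=1e-10)


class TestFit:
    def test_toy_mle_matches_grid_search(self):
        recs = toy_cohort(n=12, seed=3)
        res = fit(recs, "SNP1", toy_curve_padded(), min_stratum_size=1,
                  robust=False, compute_cov=False)
        beta_grid, _ = grid_mle_single(recs, "SNP1", TOY_HAZ + [0.0])
        assert res.beta[0] == pytest.approx(beta_grid, abs=2e-3)

    def test_permuted_genotypes_give_null_estimate(self, small_cohort):
        rng = np.random.default_rng(99)
        doses = [r.genotypes["SNP1"] for r in small_cohort]
        perm = rng.permutation(doses)
        recs = []
        for r, g in zip(small_cohort, perm):
            r2 = make_record(0)
            recs.append(type(r)(**{**r.__dict__, "genotypes": {"SNP1": int(g)}}))
        res = fit(recs, "SNP1", default_curves("BRCA1")["breast"])
        se = res.se(robust=True)[0]
        assert abs(res.beta[0]) < 3 * se

    def test_hr_and_ci_invariant_to_stratum_relabelling(self, small_cohort):
        curve = default_curves("BRCA1")["breast"]
        base = fit(small_cohort, "SNP1", curve)
        relabelled = [type(r)(**{**r.__dict__, "country": "Z" + r.country})
                      for r in small_cohort]
        again = fit(relabelled, "SNP1", curve)
        for k in ("hr", "ci_low", "ci_high"):
            assert base.hazard_ratios()[0][k] == pytest.approx(
                again.hazard_ratios()[0][k], rel=1e-5)

    def test_requires_both_affected_and_unaffected(self):
        recs = [make_record(i, genotypes={"SNP1": 1}) for i in range(5)]
        with pytest.raises(ValueError, match="affected"):
            fit(recs, "SNP1", toy_curve_padded())

    def test_genotype2df_reports_het_and_hom_ratios(self, small_cohort):
        res = fit(small_cohort, "SNP1", default_curves("BRCA1")["breast"],
                  EffectSpec("genotype2df"))
        hrs = {h["param"]: h for h in res.hazard_ratios()}
        assert set(hrs) == {"beta_het", "beta_hom"}
        assert "genotype_2df_lrt" in res.tests
        assert res.tests["genotype_2df_lrt"]["df"] == 2


class TestAgeInteraction:
    def test_null_data_gives_moderate_statistic(self, small_cohort):
        out = age_interaction_test(small_cohort, "SNP1",
                                   default_curves("BRCA1")["breast"])
        assert out["df"] == 1 and 0.0 <= out["p"] <= 1.0

    def test_degenerate_age_data_raises(self):
        recs = [make_record(i, age_last_obs=40, bc_age=40,
                            genotypes={"SNP1": i % 3}) for i in range(6)]
        recs += [make_record(10 + i, age_last_obs=40,
                             genotypes={"SNP1": i % 3}) for i in range(6)]
        with pytest.raises(ValueError, match="age variation"):
            age_interaction_test(recs, "SNP1", toy_curve_padded(),
                                 min_stratum_size=1)

    def test_detects_age_varying_effect(self):
        # simulate a strongly age-increasing per-allele effect
        cfg = SimConfig(seed=88, n_families=900, n_strata=1,
                        beta_breast=-0.1, beta_age=0.45)
        recs = simulate_cohort(cfg)
        out = age_interaction_test(recs, "SNP1",
                                   default_curves("BRCA1")["breast"])
        assert out["beta_age"] > 0
        # null comparison at matched size: interaction evidence is stronger
        cfg0 = SimConfig(seed=88, n_families=900, n_strata=1,
                         beta_breast=-0.1, beta_age=0.0)
        out0 = age_interaction_test(simulate_cohort(cfg0), "SNP1",
                                    default_curves("BRCA1")["breast"])
        assert out["statistic"] > out0["statistic"]


class TestHeterogeneity:
    def test_identical_strata_give_zero_statistic(self):
        recs = toy_cohort(n=40, seed=10)
        copy = [type(r)(**{**r.__dict__, "country": "C01",
                           "individual_id": "X" + r.individual_id,
                           "family_id": "G" + r.family_id})
                for r in recs]
        out = heterogeneity_test(recs + copy, "SNP1", toy_curve_padded())
        assert out["statistic"] == pytest.approx(0.0, abs=1e-5)
        assert out["p"] == pytest.approx(1.0, abs=1e-4)

    def test_single_stratum_raises(self):
        recs = toy_cohort(n=20, seed=11)
        with pytest.raises(ValueError, match="2 strata"):
            heterogeneity_test(recs, "SNP1", toy_curve_padded())

    def test_detects_opposite_effects_across_strata(self):
        a = simulate_cohort(SimConfig(seed=21, n_families=900, n_strata=1,
                                      beta_breast=np.log(0.8)))[:1500]
        b = simulate_cohort(SimConfig(seed=22, n_families=900, n_strata=1,
                                      beta_breast=np.log(1.25)))[:1500]
        b = [type(r)(**{**r.__dict__, "country": "C90",
                        "individual_id": "B" + r.individual_id,
                        "family_id": "B" + r.family_id}) for r in b]
        out = heterogeneity_test(a + b, "SNP1",
                                 default_curves("BRCA1")["breast"])
        assert out["p"] < 0.05


class TestGroupDifference:
    def test_identical_groups_give_zero(self, small_cohort):
        curve = default_curves("BRCA1")["breast"]
        f = fit(small_cohort, "SNP1", curve)
        out = group_difference_test(fits={"a": f, "b": f})
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_empty_group_raises(self, small_cohort):
        with pytest.raises(ValueError, match="2 groups"):
            group_difference_test(
                records=small_cohort, group_of=lambda r: "only",
                snp="SNP1", curve=default_curves("BRCA1")["breast"])

    def test_distinguishes_protective_from_null_group(self):
        curve = default_curves("BRCA1")["breast"]
        rej = 0
        reps = 12
        for k in range(reps):
            a = simulate_cohort(SimConfig(seed=1600 + k, n_families=1800,
                                          n_strata=1,
                                          beta_breast=np.log(0.82)))[:3000]
            b = simulate_cohort(SimConfig(seed=1700 + k, n_families=1800,
                                          n_strata=1, beta_breast=0.0))[:3000]
            fa = fit(a, "SNP1", curve)
            fb = fit(b, "SNP1", curve)
            out = group_difference_test(fits={"protective": fa, "null": fb})
            rej += out["p"] < 0.05
        assert rej > reps / 2


class TestExcludePrevalent:
    def test_diagnosis_six_years_before_recruitment_excluded(self):
        rec = make_record(0, bc_age=40, recruitment_age=46)
        assert exclude_prevalent([rec]) == []

    def test_five_year_boundary_retained(self):
        rec = make_record(0, bc_age=40, recruitment_age=45)
        assert exclude_prevalent([rec]) == [rec]

    def test_unaffected_always_retained(self):
        rec = make_record(0, recruitment_age=55)
        assert exclude_prevalent([rec]) == [rec]

    def test_missing_recruitment_age_retained(self):
        rec = make_record(0, bc_age=30)
        assert exclude_prevalent([rec]) == [rec]
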