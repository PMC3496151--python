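"""Competing-risks and ER-subtype model extensions."""

import numpy as np
import pytest

from carriermod import (
    EffectSpec,
    IncidenceCurve,
    SimConfig,
    SubtypeProportions,
    default_curves,
    fit,
    fit_competing,
    fit_subtype,
    simulate_cohort,
)

from conftest import N_AGES, make_record
from oracles import grid_mle_competing, oracle_loglik_competing

TOY_B = [0.12, 0.16, 0.14]
TOY_O = [0.05, 0.07, 0.06]


def padded(vals, disease="breast"):
    h = np.zeros(N_AGES)
    h[:3] = vals
    return IncidenceCurve(disease, "BRCA1", h)


def toy_competing_cohort(n=15, seed=12, q=0.35, beta_b=0.4, beta_o=-0.5):
    """Tiny competing-risks cohort on the first three age intervals."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        dose = int(rng.binomial(2, q))
        bc = oc = None
        end = 21
        for k in range(3):
            lb = TOY_B[k] * np.exp(beta_b * dose)
            lo = TOY_O[k] * np.exp(beta_o * dose)
            if rng.random() < 1 - np.exp(-(lb + lo)):
                if rng.random() < lb / (lb + lo):
                    bc = 18 + k
                else:
                    oc = 18 + k
                end = 18 + k
                break
        recs.append(make_record(
            i, age_last_obs=end if bc is None and oc is None else end + 1,
            bc_age=bc, oc_age=oc, genotypes={"SNP1": dose}))
    return recs


class TestCompeting:
    def test_missing_ovarian_curve_is_configuration_error(self, small_cohort):
        with pytest.raises(ValueError, match="ovarian incidence"):
            fit_competing(small_cohort, "SNP1",
                          default_curves("BRCA1")["breast"], None)

    def test_zero_ovarian_incidence_reduces_to_single_disease(self):
        zero_ov = IncidenceCurve("ovarian", "BRCA1", np.zeros(N_AGES))
        curves = {"breast": default_curves("BRCA1")["breast"],
                  "ovarian": zero_ov}
        recs = simulate_cohort(SimConfig(seed=5, n_families=600,
                                         curves=curves))
        single = fit(recs, "SNP1", curves["breast"], robust=False,
                     compute_cov=False)
        comp = fit_competing(recs, "SNP1", curves["breast"], zero_ov,
                             robust=False, compute_cov=False)
        assert abs(single.beta[0] - comp.beta[0]) < 1e-6

    def test_zero_betas_reduce_to_genotype_prior(self):
        recs = toy_competing_cohort()
        want = oracle_loglik_competing(recs, "SNP1", 0.0, 0.0, 0.3,
                                       TOY_B + [0.0], TOY_O + [0.0])
        q = 0.3
        doses = [r.genotypes["SNP1"] for r in recs]
        p = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        expect = sum(np.log(p[g]) for g in doses)
        assert want == pytest.approx(expect, abs=1e-12)

    def test_toy_mle_matches_2d_grid_search(self):
        recs = toy_competing_cohort()
        res = fit_competing(recs, "SNP1", padded(TOY_B),
                            padded(TOY_O, "ovarian"), min_stratum_size=1,
                            robust=False, compute_cov=False)
        (bb, bo), _ = grid_mle_competing(recs, "SNP1", TOY_B + [0.0],
                                         TOY_O + [0.0])
        assert res.beta[0] == pytest.approx(bb, abs=2e-3)
        assert res.beta[1] == pytest.approx(bo, abs=2e-3)

    def test_estimates_invariant_to_disease_label_order(self):
        # swapping which disease is "breast" vs "ovarian" in the input data
        # swaps the parameter estimates exactly
        recs = toy_competing_cohort(seed=20)
        swapped = [type(r)(**{**r.__dict__, "bc_age": r.oc_age,
                              "oc_age": r.bc_age}) for r in recs]
        a = fit_competing(recs, "SNP1", padded(TOY_B),
                          padded(TOY_O, "ovarian"), min_stratum_size=1,
                          robust=False, compute_cov=False)
        b = fit_competing(swapped, "SNP1", padded(TOY_O),
                          padded(TOY_B, "ovarian"), min_stratum_size=1,
                          robust=False, compute_cov=False)
        assert a.beta[0] == pytest.approx(b.beta[1], abs=1e-5)
        assert a.beta[1] == pytest.approx(b.beta[0], abs=1e-5)

    def test_recovers_both_cause_specific_effects(self):
        cfg = SimConfig(seed=31, n_families=2500, n_strata=1,
                        beta_breast=np.log(0.9), beta_ovarian=np.log(1.4))
        recs = simulate_cohort(cfg)
        res = fit_competing(recs, "SNP1",
                            default_curves("BRCA1")["breast"],
                            default_curves("BRCA1")["ovarian"])
        hrs = {h["param"]: h for h in res.hazard_ratios()}
        assert hrs["beta_breast"]["ci_low"] < 0.9 < hrs["beta_breast"]["ci_high"]
        assert hrs["beta_ovarian"]["ci_low"] < 1.4 < hrs["beta_ovarian"]["ci_high"]


class TestSubtypeProportions:
    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SubtypeProportions(np.array([0.5, 1.2]))

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "props.csv"
        path.write_text("age,pi_pos\n18,0.2\n19,0.3\n")
        props = SubtypeProportions.from_csv(path)
        np.testing.assert_allclose(props.pi_pos, [0.2, 0.3])


class TestSubtype:
    def test_all_positive_drops_negative_parameter(self):
        props = SubtypeProportions(np.ones(N_AGES))
        recs = simulate_cohort(SimConfig(seed=6, n_families=600,
                                         subtype_props=props))
        single = fit(recs, "SNP1", default_curves("BRCA1")["breast"],
                     robust=False, compute_cov=False)
        sub = fit_subtype(recs, "SNP1", default_curves("BRCA1")["breast"],
                          props=props, robust=False, compute_cov=False)
        assert sub.param_names[: sub.n_beta] == ["beta_pos"]
        assert abs(sub.beta[0] - single.beta[0]) < 1e-6

    def test_equal_effect_constraint_reduces_to_single_disease(self):
        recs = simulate_cohort(SimConfig(seed=5, n_families=600))
        single = fit(recs, "SNP1", default_curves("BRCA1")["breast"],
                     robust=False, compute_cov=False)
        sub = fit_subtype(recs, "SNP1", default_curves("BRCA1")["breast"],
                          gene="BRCA1", constrain_equal=True, robust=False,
                          compute_cov=False)
        assert abs(sub.beta[0] - single.beta[0]) < 1e-6

    def test_recovers_er_negative_specific_effect(self):
        truth = np.log(0.81)
        cfg = SimConfig(seed=301, n_families=2500, n_strata=1,
                        beta_pos=0.0, beta_neg=truth,
                        subtype_missing_rate=0.30)
        recs = simulate_cohort(cfg)
        res = fit_subtype(recs, "SNP1", default_curves("BRCA1")["breast"],
                          gene="BRCA1")
        hrs = {h["param"]: h for h in res.hazard_ratios()}
        assert hrs["beta_neg"]["ci_low"] < 0.81 < hrs["beta_neg"]["ci_high"]
        assert "subtype_difference" in res.tests

    def test_missingness_inflates_se_without_bias(self):
        # raising MAR subtype missingness must cost precision, not validity
        ses = {}
        betas = {}
        for rate in (0.0, 0.6):
            b, s = [], []
            for k in range(8):
                cfg = SimConfig(seed=4000 + k, n_families=1200, n_strata=1,
                                beta_pos=0.0, beta_neg=np.log(0.81),
                                subtype_missing_rate=rate)
                recs = simulate_cohort(cfg)[:2000]
                res = fit_subtype(recs, "SNP1",
                                  default_curves("BRCA1")["breast"],
                                  gene="BRCA1", robust=False)
                i = res.param_names.index("beta_neg")
                b.append(res.beta[i])
                s.append(res.se(robust=False)[i])
            ses[rate] = np.mean(s)
            betas[rate] = np.mean(b)
        assert ses[0.6] > ses[0.0]
        for rate in (0.0, 0.6):
            assert betas[rate] == pytest.approx(np.log(0.81), abs=0.06)

    def test_observed_subtype_with_zero_proportion_rejected(self):
        recs = [make_record(0, bc_age=40, er_status="neg",
                            genotypes={"SNP1": 1}),
                make_record(1, genotypes={"SNP1": 0})]
        props = SubtypeProportions(np.ones(N_AGES))
        with pytest.raises(ValueError, match="pi_neg"):
            fit_subtype(recs, "SNP1", default_curves("BRCA1")["breast"],
                        props=props, min_stratum_size=1, robust=False,
                        compute_cov=False)
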