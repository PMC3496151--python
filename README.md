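# carriermod

Retrospective-likelihood association analysis for **genetic modifiers of
breast and ovarian cancer risk in BRCA1/BRCA2 mutation carriers**.

Carrier cohorts are assembled through cancer-genetics clinics, so affected
women are heavily over-represented and relatives are recruited together.
Naive survival analysis of such a cohort is biased by this
outcome-dependent ascertainment.  `carriermod` implements the standard
remedy used by carrier consortia: model the **retrospective likelihood of
the observed genotypes conditional on the disease phenotypes**,

```
L_i = P(pheno_i | g_i) p_{g_i}(c_i) / Σ_g P(pheno_i | g) p_g(c_i),
```

where `p_g(c)` is the Hardy–Weinberg genotype prior at the (jointly
estimated) minor-allele frequency of country stratum `c`, and
`P(pheno | g)` follows a proportional-hazards model
`λ_g(t) = λ0(t) r_g(t)` with `r_g(t) = exp(β z_g)` (per-allele/trend or
2-df genotype parametrization, optionally with a genotype × age
interaction).  The baseline `λ0(t)` is not free: it is constrained so that
the genotype-averaged hazard reproduces an external carrier incidence
(penetrance) curve at every age.  Because the likelihood conditions on
phenotype, clinic-style oversampling of affected carriers does not bias
the hazard-ratio estimates.

The package provides, as both a Python library and a `carriermod` CLI:

- **data_io** — TSV carrier tables, CSV incidence curves, eligibility
  rules (double-carrier and duplicate exclusion), and the censoring rules
  that derive follow-up (first of breast cancer, ovarian cancer,
  prophylactic mastectomy, or last observation).
- **qc** — the genotyping quality-control pipeline: per-sample
  missingness (≥ 5 failed calls of 26 SNPs), per-study call rate
  (strictly > 95%), duplicate concordance (≥ 98%), cross-centre test-plate
  consistency (fail on > 1 discordant sample), per-study Hardy–Weinberg
  tests on unrelated subjects, and duplicate-subject detection.
- **hazard_core / retro_inference** — the constrained-baseline machinery
  and maximum-likelihood fits with per-allele HRs, Wald 95% CIs from
  family-cluster **robust (sandwich) covariance**, likelihood-ratio
  P-trend and 2-df tests, genotype × age interaction, between-stratum
  heterogeneity, group-difference (e.g. mutation class) tests, and
  prevalent-case sensitivity exclusion.
- **competing_subtype** — simultaneous breast/ovarian cause-specific HRs
  (competing risks) and ER-subtype-specific HRs with
  missing-at-random subtype labels.
- **synthetic_data** — a generator of clinic-ascertained carrier cohorts
  (HWE founder genotypes, sibling allele sharing, competing
  genotype-specific yearly hazards, surgeries, affected-oversampled
  recruitment) so the whole pipeline is testable without consortium data.

## Worked example

Simulate a 400-family BRCA1-like cohort and fit the per-allele model
(the packaged incidence curves are illustrative constants, not cohort
estimates):

```bash
carriermod simulate --seed 7 --n-families 400 --out cohort.tsv
carriermod fit --table cohort.tsv --snp SNP1 --gene BRCA1 --out report.json
```

The simulate step prints a cohort summary (672 carriers, 342 with breast
cancer, 29,293 person-years, median censoring age 42, IQR 34–51), and the
fit report contains:

```json
"hazard_ratios": [
  {
    "param": "beta",
    "hr": 0.9517105179522503,
    "ci_low": 0.7734911637444054,
    "ci_high": 1.1709932219474457,
    "p_wald": 0.6398917137060507
  }
],
"tests": {
  "trend_lrt": {"statistic": 0.1989..., "df": 1, "p": 0.6556...}
}
```

i.e. an estimated per-allele hazard ratio of 0.95 (95% CI 0.77–1.17,
robust Wald) with likelihood-ratio P-trend 0.66 — consistent with the
generative truth (HR 0.87) at this small cohort size.  `fit-competing`
adds a simultaneous ovarian-cancer HR, and `fit-subtype` splits the
breast-cancer effect by tumour ER status with a Wald test on the
difference.

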