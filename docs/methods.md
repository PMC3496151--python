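# Methods

## Model

The analysis population is women carrying a pathogenic BRCA1 or BRCA2
mutation, followed from age 18 for a first breast cancer (and, in the
competing-risks extension, ovarian cancer).  A candidate modifier SNP with
minor-allele dose `g ∈ {0,1,2}` acts multiplicatively on the
cause-specific hazard:

    λ_g(t) = λ0(t) · r_g(t)

on yearly intervals `[t, t+1)`, with `r_g(t) = exp(β z_g)` where `z_g = g`
(trend model) or free heterozygote/homozygote indicators (2-df model).
With the genotype × age interaction the per-allele log-HR drifts linearly,
`β(t) = β0 + β1 (t − 40)/10`; 40 is near the median censoring age of
clinic cohorts and the divisor expresses the slope per decade.

### Incidence-constrained baseline

Carrier incidence (penetrance) curves `λ*(t)` are an external input; the
baseline is defined by requiring that the genotype-averaged hazard among
still-unaffected carriers equal `λ*(t)` at every age.  Writing
`S_g(t) = exp(−Σ_{u<t} λ0(u) r_g(u))` and HWE weights
`p_g = ((1−q)², 2q(1−q), q²)`:

    λ0(t) = λ*(t) · Σ_g p_g S_g(t) / Σ_g p_g S_g(t) r_g(t),

computed forward in age from `S_g(18) = 1`.  For competing causes the
joint survival `exp(−Σ_d cumhaz_{d,g}(t))` replaces `S_g` in both causes'
constraints, preserving each cause's marginal identity.  The recursion is
our reconstruction of the standard kin-cohort construction; it is pinned
by a property test (and an acceptance check) that the reconstructed
marginal hazard matches the input curve to 1e-10 at every age for random
(maf, β, curve) draws.

### Retrospective likelihood

Each carrier contributes the probability of her genotype given her
phenotype,

    ℓ_i = log [ L_i(g_i) p_{g_i}(c_i) / Σ_g L_i(g) p_g(c_i) ],

where `L_i(g)` is the phenotype likelihood: `S_g(T)` for a carrier
censored at `T`, and `S_g(t) · λ0(t) r_g(t)` (event density) for a
diagnosis at `t`.  Conditioning on phenotype is what makes the estimator
insensitive to phenotype-based (clinic) ascertainment.  Analyses are
stratified by country (studies from one country pooled; strata under 10
carriers grouped), and the per-stratum allele frequencies `q_c` are free
parameters estimated jointly with β.

Censoring follows the consortium conventions.  Breast-only analysis:
follow-up ends at the first of breast cancer, ovarian cancer, bilateral
prophylactic mastectomy, or last observation; only breast cancer counts as
affected.  Competing analysis: follow-up ends at the first cancer with
that cause; breast follow-up is additionally censored at mastectomy and
ovarian follow-up at oophorectomy.  Ages are integer years; ties resolve
breast > ovarian > mastectomy > last observation (a stated convention —
the field's sources do not specify tie-breaks).  Events use the density
`S(t)λ(t)` rather than the interval probability `S(t)(1−e^{−λ})`; with the
generator operating on the same discrete-yearly grid, small-sample oracle
comparisons are exact, not approximate.

### Extensions

*Competing risks.*  Breast and ovarian log-HRs are estimated jointly,
assuming the two diseases independent conditional on genotype (no shared
frailty).  Each cause's baseline is constrained to its own incidence
curve.

*ER subtype.*  The breast hazard splits as
`λ_{g,s}(t) = λ0(t) π_s(t) exp(β_s g)` with `π_s(t)` the age-indexed
ER-positive/negative split of carrier tumours.  The aggregate
`r_g(t) = Σ_s π_s(t) exp(β_s g)` feeds the baseline constraint; tumours of
known subtype contribute their subtype's density, unknown subtypes the sum
over subtypes (missing at random).  The packaged `π` defaults are
illustrative step functions (BRCA1 0.22 → 0.35 at 50; BRCA2 0.72 → 0.80)
and must be replaced by pathology-based estimates for real analyses; they
are user-replaceable via `--props`.  A subtype with `π ≡ 0` carries no
estimable parameter and is dropped from the parameter vector.

### Inference

The joint MLE over (β, logit q_c) is found by BFGS with explicit
central-difference gradients (relative step 1e-5); a fit is flagged
converged only when the gradient sup-norm falls below 1e-4.  Covariance is
reported both model-based (inverse observed information, central
second differences) and cluster-robust by family:
`A⁻¹BA⁻¹` with `A` the observed information and `B` the sum of outer
products of per-family score sums.  No finite-cluster correction is
applied by default (a `G/(G−1)` factor is available behind a flag).
Robust covariance backs all reported CIs and Wald tests; LRTs (P-trend,
2-df, interaction, heterogeneity) are model-based, as is standard.  The
null for the trend/2-df LRT is available in closed form: with all effects
zero the retrospective likelihood reduces to the HWE multinomial, whose
per-stratum MLE is the empirical allele frequency.  P-trend defaults to
the 1-df LRT; Wald and efficient-score versions are also reported.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: HWE parental
genotypes per country stratum with siblings drawing alleles from shared
parents (sibship sizes uniform 1–4); yearly competing event draws with
probability `1 − exp(−λ_B,g − λ_O,g)` and cause proportional to the
cause-specific hazards, where the genotype-specific hazards come from the
same incidence-constrained construction at the configured true effects (so
the analysis model is correctly specified by construction); ER subtype
drawn ∝ `π_s(t) e^{β_s g}` then masked at the configured
missing-at-random rate; surgeries as yearly Bernoulli draws (defaults
0.002/yr mastectomy, 0.005/yr oophorectomy from age 30) that zero the
matching hazard; administrative censoring uniform on ages 25–79; and
clinic-style recruitment in which affected carriers are probands with 5×
the weight of unaffected ones and each proband's relatives join with
probability 0.5.  Default generative effects are a per-allele breast HR of
0.87 with a null ovarian effect.  The packaged incidence curves are round
piecewise constants chosen so cumulative breast risk to 70 is in the
high-penetrance range (≈61% BRCA1, ≈45% BRCA2); they are deliberately
labelled illustrative and are not estimates from any cohort.

What the generator does **not** emulate: multi-generation pedigrees,
calendar-period and cohort-band incidence variation, mutation-position-
specific penetrance, genotyping-intensity artefacts, or informative
(non-MAR) pathology reporting.  Passing tests therefore demonstrate
correctness of the estimator under its own assumptions and robustness to
outcome-dependent sampling — not robustness to model misspecification in
real consortium data.

## Numerical choices and edge cases

- Age grid 18–80, hazard zero outside; follow-up indices clamp to the
  grid (exact, since the hazard vanishes there).
- Allele frequencies are optimized on the logit scale; starting values are
  the empirical per-stratum frequencies clipped to [0.005, 0.995].
- An event at an age where the supplied incidence curve is zero is
  rejected as a data/configuration inconsistency before fitting.
- Monomorphic genotype counts give an HWE statistic of 0 (p = 1); HWE
  studies with p < 0.005 are excluded, p in [0.005, 0.05) flagged for
  review (a logged warning stands in for cluster-plot inspection).
  Unrelated subjects for HWE are one member per family, the lowest
  individual id.
- The sample-missingness rule is an explicit count,
  `max(1, round(0.20 · n_snps))`, so 26 typed SNPs give a cutoff of five
  missing calls; a pure fraction rule would give six and is rejected.
- Duplicate-concordance with zero comparable pairs passes with a warning.

## Direction of the cluster-robust adjustment

A duplication identity is the signature that clustering is honoured:
stacking every family twice leaves the sandwich covariance exactly
unchanged while halving the model-based covariance.  The *direction* of
the robust adjustment, however, depends on the within-family phenotype
mix, not on genotype correlation alone: affected and unaffected relatives
contribute opposite-signed score contributions on a shared genotype draw,
so in mixed-status clinic families the within-family score covariance is
typically negative and the robust SE falls slightly below the naive SE.
When family members' contributions are positively correlated (e.g.
duplicated phenotype+genotype records), the robust SE exceeds the naive
one, as classical intuition suggests.  Both regimes are covered by tests.

## Problem sizes used by the test suite

Replicate-based checks use cohorts of 3000 carriers (50 replicates) for
recovery of HR 0.87 under 5× oversampling and of the ER-negative HR 0.81
under 30% label missingness, 500 cohorts of 1000 carriers for P-trend
type-I error, and 10-replicate contrasts for SE-inflation comparisons;
oracle comparisons use 12–15-carrier cohorts on three-year toy grids where
brute-force enumeration and 1e-3-step grid searches are exact.  These
sizes give Monte-Carlo error comfortably inside the stated tolerances.

## Known limitations

- Untyped relatives contribute nothing: the full pedigree likelihood over
  unobserved family genotypes (as in pedigree-analysis software) is out of
  scope; family structure enters only through the robust variance.
- Calendar-year/cohort-band-specific incidence lookup is supported at the
  curve level but the generator does not produce cohort-banded data.
- The family-based recruitment of the generator (probands plus relatives)
  induces a mild residual ascertainment effect that individual-phenotype
  conditioning does not fully remove; empirically the bias is well inside
  the tested tolerances (≤ 0.01 on the log-HR at the tested sizes, against
  a ±0.03 band).
- Exact (rather than asymptotic) inference is limited to the optional HWE
  exact test; score/Wald/LRT inference is asymptotic throughout.
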