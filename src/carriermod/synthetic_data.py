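"""Synthetic clinic-ascertained carrier cohorts.

Generates mutation-carrier cohorts with the statistical structure the
retrospective-likelihood analysis assumes, so every pipeline stage is
testable without consortium data:

* HWE founder genotypes per country stratum; siblings draw alleles from
  shared simulated parents (within-family genotype correlation);
* discrete-yearly competing breast/ovarian age-at-onset hazards that are
  genotype-specific via the configured log hazard ratios, with the
  genotype-averaged hazard equal to the configured incidence curve (the
  generator uses the same incidence-constrained baseline as the analysis,
  so the analysis model is correctly specified by construction);
* ER subtype drawn proportional to pi_s(t) * exp(beta_s g), with
  missing-at-random label removal;
* prophylactic mastectomy/oophorectomy as yearly Bernoulli draws that zero
  the corresponding hazard;
* outcome-dependent (clinic-style) recruitment: affected carriers are
  oversampled as probands, and each proband's relatives join with a fixed
  probability.

The packaged incidence curves are illustrative piecewise constants in the
high-penetrance range — deliberately NOT external cohort estimates.
Simulation is discrete-yearly on the analysis age grid, so small-sample
oracle comparisons are exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .competing_subtype import SubtypeProportions
from .data_io import CarrierRecord, derive_followup
from .hazard_core import (
    AGE_MAX,
    AGE_MIN,
    EffectSpec,
    GenotypeModel,
    IncidenceCurve,
    constrained_baseline_competing,
    relative_risk,
)

__all__ = ["SimConfig", "default_curves", "simulate_cohort", "summarize_cohort"]

_DOSES = np.array([0.0, 1.0, 2.0])


def default_curves(gene: str = "BRCA1") -> dict[str, IncidenceCurve]:
    """Illustrative carrier incidence curves (per-year hazards by decade).

    Chosen so cumulative breast-cancer risk to age 70 lands in the
    high-penetrance range (~60% BRCA1, ~45% BRCA2); these are round
    illustrative constants, not estimates from any cohort.
    """
    ages = np.arange(AGE_MIN, AGE_MAX)
    if gene == "BRCA1":
        breast = np.select(
            [ages < 30, ages < 40, ages < 50, ages < 60],
            [0.003, 0.015, 0.030, 0.025], default=0.020)
        ovarian = np.select(
            [ages < 40, ages < 50, ages < 60],
            [0.001, 0.010, 0.015], default=0.010)
    elif gene == "BRCA2":
        breast = np.select(
            [ages < 30, ages < 40, ages < 50, ages < 60],
            [0.001, 0.008, 0.020, 0.022], default=0.020)
        ovarian = np.select(
            [ages < 40, ages < 60], [0.0005, 0.004], default=0.006)
    else:
        raise ValueError(f"unknown gene {gene!r}")
    return {
        "breast": IncidenceCurve("breast", gene, breast, AGE_MIN),
        "ovarian": IncidenceCurve("ovarian", gene, ovarian, AGE_MIN),
    }


@dataclass
class SimConfig:
    """All generative parameters of a synthetic carrier cohort.

    Effects are log hazard ratios; ``beta_breast`` may be a scalar (trend)
    or a pair (heterozygote, homozygote).  When ``beta_pos``/``beta_neg``
    are set the breast effect acts through the ER subtypes and
    ``beta_breast`` is ignored.  ``seed`` is mandatory: the generator is
    deterministic given the seed.
    """

    seed: int
    n_families: int = 1000
    sibship_max: int = 4                      # sibship size uniform on 1..max
    n_strata: int = 2                         # country strata
    maf: float | list[float] = 0.25           # minor-allele frequency per stratum
    gene: str = "BRCA1"
    beta_breast: float | tuple[float, float] = float(np.log(0.87))
    beta_ovarian: float = 0.0
    beta_pos: float | None = None             # ER-subtype-specific effects
    beta_neg: float | None = None
    beta_age: float = 0.0                     # trend drift per decade from 40
    curves: dict[str, IncidenceCurve] | None = None
    subtype_props: SubtypeProportions | None = None
    subtype_missing_rate: float = 0.30
    mastectomy_rate: float = 0.002            # yearly, from surgery_min_age
    oophorectomy_rate: float = 0.005
    surgery_min_age: int = 30
    w_affected: float = 5.0                   # proband recruitment weights
    w_unaffected: float = 1.0
    relative_inclusion_prob: float = 0.5
    censor_age_range: tuple[int, int] = (25, 79)
    birth_year_range: tuple[int, int] = (1920, 1975)
    genotype_missing_rate: float = 0.0
    snp_name: str = "SNP1"
    extra_null_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("subtype_missing_rate", "mastectomy_rate",
                     "oophorectomy_rate", "relative_inclusion_prob",
                     "genotype_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.w_affected < 0 or self.w_unaffected < 0 \
                or max(self.w_affected, self.w_unaffected) == 0:
            raise ValueError("recruitment weights must be non-negative with "
                             "a positive maximum")
        mafs = self.maf_per_stratum()
        if any(not 0.0 < m < 1.0 for m in mafs):
            raise ValueError("maf must lie strictly in (0, 1)")

    def maf_per_stratum(self) -> list[float]:
        if isinstance(self.maf, (int, float)):
            return [float(self.maf)] * self.n_strata
        if len(self.maf) != self.n_strata:
            raise ValueError("len(maf) must equal n_strata")
        return [float(m) for m in self.maf]

    def breast_spec_and_beta(self) -> tuple[EffectSpec, np.ndarray]:
        if isinstance(self.beta_breast, (tuple, list)):
            return (EffectSpec("genotype2df"),
                    np.asarray(self.beta_breast, dtype=float))
        if self.beta_age != 0.0:
            return (EffectSpec("trend", age_interaction=True),
                    np.array([self.beta_breast, self.beta_age]))
        return EffectSpec("trend"), np.array([float(self.beta_breast)])


def _child_doses(rng: np.random.Generator, father: np.ndarray,
                 mother: np.ndarray) -> np.ndarray:
    """One allele from each simulated parent (doses are allele counts)."""
    a = rng.random(father.size) < father / 2.0
    b = rng.random(mother.size) < mother / 2.0
    return a.astype(int) + b.astype(int)


def simulate_cohort(cfg: SimConfig) -> list[CarrierRecord]:
    """Draw one clinic-ascertained carrier cohort.

    Returns validated :class:`CarrierRecord` objects (probands plus
    retained relatives), deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    ages = np.arange(AGE_MIN, AGE_MAX)
    n_ages = ages.size
    mafs = cfg.maf_per_stratum()
    curves = cfg.curves or default_curves(cfg.gene)
    props = cfg.subtype_props or SubtypeProportions.step(cfg.gene)
    pi_pos = props.on_grid(AGE_MIN, AGE_MAX)

    # effect structure: breast risk acts through subtypes when configured
    spec_b, beta_b = cfg.breast_spec_and_beta()
    subtype_specific = cfg.beta_pos is not None or cfg.beta_neg is not None
    if subtype_specific:
        b_pos = float(cfg.beta_pos or 0.0)
        b_neg = float(cfg.beta_neg or 0.0)
        r_breast = (pi_pos[None, :] * np.exp(b_pos * _DOSES)[:, None]
                    + (1 - pi_pos)[None, :] * np.exp(b_neg * _DOSES)[:, None])
    else:
        r_breast = relative_risk(spec_b, beta_b, ages)
        if isinstance(cfg.beta_breast, (tuple, list)):
            b_pos = b_neg = None
        else:
            b_pos = b_neg = float(cfg.beta_breast)
    r_ovarian = relative_risk(EffectSpec("trend"),
                              [float(cfg.beta_ovarian)], ages)

    # genotype-specific yearly hazards per stratum (marginal = input curve)
    lam_b = np.empty((cfg.n_strata, 3, n_ages))
    lam_o = np.empty((cfg.n_strata, 3, n_ages))
    for c, q in enumerate(mafs):
        bh = constrained_baseline_competing(
            curves, GenotypeModel(q),
            {"breast": r_breast, "ovarian": r_ovarian})
        lam_b[c] = bh.lam0["breast"][None, :] * r_breast
        lam_o[c] = bh.lam0["ovarian"][None, :] * r_ovarian
    p_event_max = 1.0 - np.exp(-(lam_b + lam_o).max())
    if p_event_max > 0.999:
        raise ValueError("configured hazards imply a yearly event "
                         "probability indistinguishable from 1")

    # families, strata, genotypes
    sizes = rng.integers(1, cfg.sibship_max + 1, cfg.n_families)
    fam_stratum = rng.integers(0, cfg.n_strata, cfg.n_families)
    q_by_fam = np.array(mafs)[fam_stratum]
    father = rng.binomial(2, q_by_fam)
    mother = rng.binomial(2, q_by_fam)
    fam_idx = np.repeat(np.arange(cfg.n_families), sizes)
    n = fam_idx.size
    dose = _child_doses(rng, father[fam_idx], mother[fam_idx])
    strat = fam_stratum[fam_idx]

    # per-individual hazard trajectories
    hb = lam_b[strat, dose]  # (n, T)
    ho = lam_o[strat, dose]

    c_lo, c_hi = cfg.censor_age_range
    censor = rng.integers(c_lo, c_hi + 1, n)
    bc_age = np.full(n, -1)
    oc_age = np.full(n, -1)
    mast_age = np.full(n, -1)
    ooph_age = np.full(n, -1)

    for k, t in enumerate(ages):
        at_risk = (bc_age < 0) & (oc_age < 0) & (t < censor)
        if t >= cfg.surgery_min_age:
            new_m = at_risk & (mast_age < 0) & (rng.random(n) < cfg.mastectomy_rate)
            mast_age[new_m] = t
            new_o = at_risk & (ooph_age < 0) & (rng.random(n) < cfg.oophorectomy_rate)
            ooph_age[new_o] = t
        hb_t = np.where((mast_age < 0) | (t < mast_age), hb[:, k], 0.0)
        ho_t = np.where((ooph_age < 0) | (t < ooph_age), ho[:, k], 0.0)
        tot = hb_t + ho_t
        event = at_risk & (rng.random(n) < -np.expm1(-tot))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_b = np.where(tot > 0, hb_t / np.where(tot > 0, tot, 1.0), 0.0)
        is_b = rng.random(n) < frac_b
        bc_age[event & is_b] = t
        oc_age[event & ~is_b] = t

    # ER subtype for breast cancers: P(pos) ∝ pi_pos(t) e^{beta_pos g}
    er = np.zeros(n, dtype=int)  # 0 missing, 1 pos, 2 neg
    cases = np.flatnonzero(bc_age >= 0)
    if cases.size and b_pos is not None:
        t_idx = bc_age[cases] - AGE_MIN
        w_pos = pi_pos[t_idx] * np.exp(b_pos * dose[cases])
        w_neg = (1 - pi_pos[t_idx]) * np.exp(b_neg * dose[cases])
        is_pos = rng.random(cases.size) < w_pos / (w_pos + w_neg)
        er[cases] = np.where(is_pos, 1, 2)
        er[cases[rng.random(cases.size) < cfg.subtype_missing_rate]] = 0

    # recruitment: affected probands oversampled; relatives tag along
    affected = bc_age >= 0
    recruit = np.where(affected,
                       np.minimum(censor, bc_age + rng.integers(0, 9, n)),
                       censor)
    recruit = np.maximum(recruit, 18)
    w_max = max(cfg.w_affected, cfg.w_unaffected)
    p_proband = np.where(affected, cfg.w_affected, cfg.w_unaffected) / w_max
    proband = rng.random(n) < p_proband
    fam_has = np.zeros(cfg.n_families, dtype=bool)
    np.logical_or.at(fam_has, fam_idx, proband)
    keep = proband | (fam_has[fam_idx]
                      & (rng.random(n) < cfg.relative_inclusion_prob))

    # genotypes table (analysed SNP + optional null SNPs), with missingness
    snp_names = [cfg.snp_name] + list(cfg.extra_null_snps)
    doses: dict[str, np.ndarray] = {cfg.snp_name: dose}
    for s in cfg.extra_null_snps:
        f2 = rng.binomial(2, q_by_fam)
        m2 = rng.binomial(2, q_by_fam)
        doses[s] = _child_doses(rng, f2[fam_idx], m2[fam_idx])
    missing = {s: rng.random(n) < cfg.genotype_missing_rate for s in snp_names}

    birth_year = rng.integers(cfg.birth_year_range[0],
                              cfg.birth_year_range[1] + 1, n)
    # mutation functional class (BRCA1-style labelling)
    mclass = rng.choice(np.array(["class1", "class2", "unknown"]),
                        size=n, p=[0.55, 0.30, 0.15])

    er_label = {0: None, 1: "pos", 2: "neg"}
    records: list[CarrierRecord] = []
    for i in np.flatnonzero(keep):
        fam = int(fam_idx[i])
        c = int(strat[i])
        records.append(CarrierRecord(
            individual_id=f"I{i:06d}",
            family_id=f"F{fam:05d}",
            study_id=f"ST{c:02d}",
            country=f"C{c:02d}",
            gene=cfg.gene,
            birth_year=int(birth_year[i]),
            mutation_class=str(mclass[i]),
            mutation=f"m{fam:05d}",
            age_last_obs=int(censor[i]),
            bc_age=int(bc_age[i]) if bc_age[i] >= 0 else None,
            oc_age=int(oc_age[i]) if oc_age[i] >= 0 else None,
            mastectomy_age=int(mast_age[i]) if mast_age[i] >= 0 else None,
            oophorectomy_age=int(ooph_age[i]) if ooph_age[i] >= 0 else None,
            recruitment_age=int(recruit[i]),
            er_status=er_label[int(er[i])] if bc_age[i] >= 0 else None,
            genotypes={s: (None if missing[s][i] else int(doses[s][i]))
                       for s in snp_names},
        ))
    return records


def summarize_cohort(records: list[CarrierRecord]) -> dict:
    """Cohort characteristics table: counts, person-years, censoring ages.

    Person-years are summed ages at end of (breast-only) follow-up; the
    censoring-age median/IQR and decade-of-birth histogram mirror the usual
    cohort-description layout.
    """
    if not records:
        return {"n": 0, "n_breast": 0, "n_unaffected": 0, "person_years": 0,
                "median_censor_age": 0.0, "iqr_censor_age": [0.0, 0.0],
                "birth_decades": {}, "mutation_classes": {},
                "censoring": {}}
    end_ages = []
    statuses = []
    censor_kind = {"breast": 0, "ovarian": 0, "mastectomy": 0, "last_obs": 0}
    for rec in records:
        fu = derive_followup(rec, "breast_only")
        end_ages.append(fu.end_age)
        statuses.append(fu.status)
        if fu.status == "breast":
            censor_kind["breast"] += 1
        elif rec.oc_age is not None and fu.end_age == rec.oc_age:
            censor_kind["ovarian"] += 1
        elif rec.mastectomy_age is not None and fu.end_age == rec.mastectomy_age:
            censor_kind["mastectomy"] += 1
        else:
            censor_kind["last_obs"] += 1
    end_ages = np.array(end_ages)
    n_breast = sum(s == "breast" for s in statuses)
    decades: dict[str, int] = {}
    for rec in records:
        key = f"{(rec.birth_year // 10) * 10}s"
        decades[key] = decades.get(key, 0) + 1
    classes: dict[str, int] = {}
    for rec in records:
        classes[rec.mutation_class] = classes.get(rec.mutation_class, 0) + 1
    q25, q50, q75 = np.percentile(end_ages, [25, 50, 75])
    return {
        "n": len(records),
        "n_breast": int(n_breast),
        "n_unaffected": int(len(records) - n_breast),
        "person_years": int(end_ages.sum()),
        "median_censor_age": float(q50),
        "iqr_censor_age": [float(q25), float(q75)],
        "birth_decades": dict(sorted(decades.items())),
        "mutation_classes": dict(sorted(classes.items())),
        "censoring": censor_kind,
    }
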