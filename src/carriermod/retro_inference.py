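"""Maximum-likelihood inference under the retrospective likelihood.

Carrier cohorts are recruited through clinics, so sampling depends on
phenotype.  The analysis therefore maximizes the *retrospective* likelihood
of the observed genotypes given the phenotypes,

    L = prod_i  P(pheno_i | g_i) p_{g_i}(c_i) / sum_g P(pheno_i | g) p_g(c_i),

which is insensitive to phenotype-based ascertainment.  ``P(pheno | g)``
comes from genotype-specific survival under the incidence-constrained
baseline hazard (see :mod:`carriermod.hazard_core`); ``p_g(c)`` is the HWE
genotype prior at the stratum-specific allele frequency ``q_c``.  Analyses
are stratified by country (studies from the same country grouped), and the
per-stratum allele frequencies are estimated jointly with the log hazard
ratios.

Reported covariance is both model-based (inverse observed information) and
cluster-robust by family (sandwich); Wald CIs use the robust covariance,
likelihood-ratio tests the model-based likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from . import robust_variance
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

logger = logging.getLogger("carriermod")

__all__ = [
    "AnalysisData",
    "FitResult",
    "SingleDiseaseModel",
    "build_analysis_data",
    "retro_loglik",
    "fit",
    "test_age_interaction",
    "test_heterogeneity",
    "test_group_difference",
    "exclude_prevalent",
]


# ---------------------------------------------------------------------------
# dataset preparation

@dataclass
class AnalysisData:
    """Vectorized per-individual arrays for one SNP analysis."""

    n: int
    dose: np.ndarray          # (n,) int minor-allele dose
    stratum: np.ndarray       # (n,) int codes into .strata
    strata: list[str]
    family: np.ndarray        # (n,) cluster labels
    end_idx: np.ndarray       # (n,) follow-up end minus age_min (breast-only)
    is_case: np.ndarray       # (n,) bool: breast cancer event (breast-only)
    bc_idx: np.ndarray        # (n,) per-disease end indices (competing)
    oc_idx: np.ndarray
    status: np.ndarray        # (n,) 0 unaffected, 1 breast, 2 ovarian
    er_code: np.ndarray       # (n,) 0 missing, 1 ER-positive, 2 ER-negative
    age_min: int = AGE_MIN
    age_max: int = AGE_MAX

    def rows_of(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.stratum == c)
                for c in range(len(self.strata))]


def build_analysis_data(
    records: list[CarrierRecord],
    snp: str,
    mode: str = "breast_only",
    stratify_by: str = "country",
    min_stratum_size: int = 10,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> AnalysisData:
    """Convert records into analysis arrays for one SNP.

    Records with a missing genotype for the analysed SNP are dropped
    (complete-case per SNP, logged).  Strata with fewer carriers than
    ``min_stratum_size`` are grouped into a pooled stratum.
    """
    usable = [r for r in records if r.genotypes.get(snp) is not None]
    n_dropped = len(records) - len(usable)
    if n_dropped:
        logger.info("%s: dropped %d record(s) with missing genotype",
                    snp, n_dropped)
    if not usable:
        raise ValueError(f"no records with observed genotype for {snp}")
    raw_strata = [getattr(r, stratify_by) for r in usable]
    counts: dict[str, int] = {}
    for s in raw_strata:
        counts[s] = counts.get(s, 0) + 1
    small = {s for s, k in counts.items() if k < min_stratum_size}
    if small and len(small) < len(counts):
        grouped = [s if s not in small else "_pooled" for s in raw_strata]
    else:
        grouped = raw_strata
    strata = sorted(set(grouped))
    codes = np.array([strata.index(s) for s in grouped])

    dose = np.array([r.genotypes[snp] for r in usable], dtype=int)
    family = np.array([r.family_id for r in usable])
    end_idx = np.zeros(len(usable), dtype=int)
    is_case = np.zeros(len(usable), dtype=bool)
    bc_idx = np.zeros(len(usable), dtype=int)
    oc_idx = np.zeros(len(usable), dtype=int)
    status = np.zeros(len(usable), dtype=int)
    er_code = np.zeros(len(usable), dtype=int)
    for i, rec in enumerate(usable):
        fu_b = derive_followup(rec, "breast_only")
        fu_c = derive_followup(rec, "competing")
        # end ages are clamped to the grid: hazard is zero outside, so
        # clamping the survival index is exact; events past the grid end
        # are treated as censored at the grid end
        end_idx[i] = int(np.clip(fu_b.end_age, age_min, age_max)) - age_min
        is_case[i] = fu_b.status == "breast" and fu_b.end_age < age_max
        bc_idx[i] = int(np.clip(fu_c.bc_end, age_min, age_max)) - age_min
        oc_idx[i] = int(np.clip(fu_c.oc_end, age_min, age_max)) - age_min
        status[i] = {"unaffected": 0, "breast": 1, "ovarian": 2}[fu_c.status]
        if fu_c.status in ("breast", "ovarian") and fu_c.end_age >= age_max:
            status[i] = 0
        er_code[i] = {None: 0, "pos": 1, "neg": 2}[rec.er_status]
    return AnalysisData(
        n=len(usable), dose=dose, stratum=codes, strata=strata, family=family,
        end_idx=end_idx, is_case=is_case, bc_idx=bc_idx, oc_idx=oc_idx,
        status=status, er_code=er_code, age_min=age_min, age_max=age_max,
    )


# ---------------------------------------------------------------------------
# model definitions

class SingleDiseaseModel:
    """Breast-cancer-only model: one cause, trend or 2-df genotype effect."""

    mode = "breast_only"

    def __init__(self, spec: EffectSpec, curve: IncidenceCurve,
                 age_min: int = AGE_MIN, age_max: int = AGE_MAX):
        self.spec = spec
        self.curve = curve
        self.age_min = age_min
        self.age_max = age_max
        self.ages = np.arange(age_min, age_max)

    @property
    def n_beta(self) -> int:
        return self.spec.n_params

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names

    def baseline(self, gm: GenotypeModel, beta: np.ndarray):
        r = relative_risk(self.spec, beta, self.ages)
        return constrained_baseline_competing(
            {"breast": self.curve}, gm, {"breast": r},
            self.age_min, self.age_max)

    def loglik_matrix(self, ds: AnalysisData, rows: np.ndarray, bh,
                      beta: np.ndarray) -> np.ndarray:
        cum = bh.cumhaz["breast"]
        m = -cum[:, ds.end_idx[rows]].T
        ev = ds.is_case[rows]
        if ev.any():
            t = ds.end_idx[rows][ev]
            m[ev] += np.log(bh.lam0["breast"][t][:, None]
                            * bh.r["breast"][:, t].T)
        return m


# ---------------------------------------------------------------------------
# likelihood engine

def _logit(q):
    return np.log(q) - np.log1p(-q)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class LikelihoodEngine:
    """Retrospective log-likelihood as a function of (beta, logit q)."""

    def __init__(self, model, ds: AnalysisData,
                 stratum_specific_beta: bool = False):
        self.model = model
        self.ds = ds
        self.k = len(ds.strata)
        self.ssb = stratum_specific_beta
        self.nb = model.n_beta * (self.k if stratum_specific_beta else 1)
        self.rows = ds.rows_of()

    @property
    def n_params(self) -> int:
        return self.nb + self.k

    @property
    def param_names(self) -> list[str]:
        if self.ssb:
            beta_names = [f"{nm}[{s}]" for s in self.ds.strata
                          for nm in self.model.param_names]
        else:
            beta_names = list(self.model.param_names)
        return beta_names + [f"logit_q[{s}]" for s in self.ds.strata]

    def unpack(self, x: np.ndarray):
        beta_block = x[: self.nb]
        qs = _expit(x[self.nb:])
        return beta_block, qs

    def beta_for(self, beta_block: np.ndarray, c: int) -> np.ndarray:
        if self.ssb:
            nb = self.model.n_beta
            return beta_block[c * nb: (c + 1) * nb]
        return beta_block

    def per_term(self, x: np.ndarray) -> np.ndarray:
        """Per-individual retrospective log-likelihood contributions."""
        beta_block, qs = self.unpack(x)
        out = np.empty(self.ds.n)
        for c, rows in enumerate(self.rows):
            if rows.size == 0:
                continue
            beta_c = self.beta_for(beta_block, c)
            gm = GenotypeModel(qs[c])
            bh = self.model.baseline(gm, beta_c)
            m = self.model.loglik_matrix(self.ds, rows, bh, beta_c)
            a = m + np.log(gm.probs)[None, :]
            lse = logsumexp(a, axis=1)
            out[rows] = a[np.arange(rows.size), self.ds.dose[rows]] - lse
        return out

    def total(self, x: np.ndarray) -> float:
        return float(self.per_term(x).sum())

    def grad(self, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
        g = np.empty(x.size)
        for j in range(x.size):
            h = step * max(1.0, abs(x[j]))
            up, dn = x.copy(), x.copy()
            up[j] += h
            dn[j] -= h
            g[j] = (self.total(up) - self.total(dn)) / (2.0 * h)
        return g

    def q0(self) -> np.ndarray:
        """Per-stratum empirical allele frequencies (starting values)."""
        q = np.empty(self.k)
        for c, rows in enumerate(self.rows):
            d = self.ds.dose[rows]
            q[c] = d.sum() / (2.0 * max(1, d.size))
        return np.clip(q, 0.005, 0.995)

    def null_loglik(self) -> float:
        """Maximized log-likelihood with all genotype effects zero.

        With beta = 0 the phenotype factor is genotype-free, so the
        retrospective likelihood reduces to the HWE multinomial and the
        per-stratum MLE of q is the empirical allele frequency.
        """
        total = 0.0
        for rows in self.rows:
            d = self.ds.dose[rows]
            m = d.size
            if m == 0:
                continue
            n1 = int((d == 1).sum())
            n2 = int((d == 2).sum())
            n0 = m - n1 - n2
            qhat = (n1 + 2 * n2) / (2.0 * m)
            p = np.array([(1 - qhat) ** 2, 2 * qhat * (1 - qhat), qhat**2])
            for count, pg in zip((n0, n1, n2), p):
                if count > 0:
                    total += count * np.log(pg)
        return total


# ---------------------------------------------------------------------------
# fit results

@dataclass
class FitResult:
    """Estimates, covariances and tests from one retrospective-likelihood fit."""

    param_names: list[str]
    estimates: np.ndarray          # full vector (beta block, logit q)
    n_beta: int
    strata: list[str]
    loglik: float
    loglik_null: float
    cov_model: np.ndarray | None
    cov_robust: np.ndarray | None
    converged: bool
    n_iter: int
    n_used: int
    n_cases: int
    tests: dict[str, dict] = field(default_factory=dict)
    genotype_counts: dict[str, list[int]] = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return self.estimates[: self.n_beta]

    @property
    def q(self) -> dict[str, float]:
        return {s: float(_expit(v)) for s, v in
                zip(self.strata, self.estimates[self.n_beta:])}

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if (robust and self.cov_robust is not None) \
            else self.cov_model
        if cov is None:
            return np.full(self.n_beta, np.nan)
        return np.sqrt(np.clip(np.diag(cov)[: self.n_beta], 0, None))

    def hazard_ratios(self, robust: bool = True) -> list[dict]:
        """Per-parameter HR with Wald 95% CI (robust SE by default)."""
        se = self.se(robust)
        out = []
        for name, b, s in zip(self.param_names[: self.n_beta], self.beta, se):
            z = b / s if s > 0 else np.nan
            out.append({
                "param": name,
                "log_hr": float(b),
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.959964 * s)),
                "ci_high": float(np.exp(b + 1.959964 * s)),
                "se": float(s),
                "p_wald": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z)
                          else np.nan,
            })
        return out

    def summary(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_cases": self.n_cases,
            "genotype_counts": self.genotype_counts,
            "converged": self.converged,
            "loglik": self.loglik,
            "hazard_ratios": self.hazard_ratios(),
            "allele_frequencies": self.q,
            "tests": self.tests,
        }


# ---------------------------------------------------------------------------
# maximization

def maximize_engine(
    engine: LikelihoodEngine,
    beta0: np.ndarray | None = None,
    robust: bool = True,
    compute_cov: bool = True,
    max_iter: int = 300,
) -> FitResult:
    """Quasi-Newton maximization with numerical central-difference gradients."""
    ds = engine.ds
    x0 = np.zeros(engine.n_params)
    if beta0 is not None:
        x0[: engine.nb] = beta0
    x0[engine.nb:] = _logit(engine.q0())

    neg = lambda x: -engine.total(x)
    neg_grad = lambda x: -engine.grad(x)
    res = optimize.minimize(neg, x0, jac=neg_grad, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": max_iter})
    xhat = res.x
    grad = engine.grad(xhat)
    converged = bool(res.success or np.max(np.abs(grad)) < 1e-4)
    if not converged:
        logger.warning("fit did not converge: |grad|_inf=%.3g after %d iters",
                       np.max(np.abs(grad)), res.nit)

    cov_model = cov_robust = None
    if compute_cov:
        hess = robust_variance.numeric_hessian(engine.total, xhat)
        try:
            cov_model = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            logger.warning("observed information singular; no model covariance")
        if robust and cov_model is not None:
            scores = robust_variance.numeric_scores(engine.per_term, xhat)
            try:
                cov_robust = robust_variance.sandwich_cov(
                    scores, hess, clusters=ds.family)
            except np.linalg.LinAlgError as exc:
                logger.warning("robust covariance unavailable: %s", exc)

    counts = {}
    for label, mask in (("unaffected", ~ds.is_case), ("breast", ds.is_case)):
        counts[label] = [int((ds.dose[mask] == g).sum()) for g in (0, 1, 2)]
    return FitResult(
        param_names=engine.param_names,
        estimates=xhat,
        n_beta=engine.nb,
        strata=ds.strata,
        loglik=float(-res.fun),
        loglik_null=engine.null_loglik(),
        cov_model=cov_model,
        cov_robust=cov_robust,
        converged=converged,
        n_iter=int(res.nit),
        n_used=ds.n,
        n_cases=int(ds.is_case.sum()),
        genotype_counts=counts,
    )


def _attach_lrt(result: FitResult, name: str, df: int) -> None:
    stat = max(0.0, 2.0 * (result.loglik - result.loglik_null))
    result.tests[name] = {
        "statistic": float(stat),
        "df": df,
        "p": float(stats.chi2.sf(stat, df)),
    }


def check_event_support(event_idx: np.ndarray, curve: IncidenceCurve,
                        cause: str, age_min: int = AGE_MIN,
                        age_max: int = AGE_MAX) -> None:
    """Fail fast when events are observed at ages of zero incidence.

    A diagnosis at an age where the supplied incidence curve is zero has
    likelihood zero under any parameter value — a data/configuration
    inconsistency, not an estimation problem.
    """
    if event_idx.size == 0:
        return
    lam = curve.on_grid(age_min, age_max)
    bad = event_idx[lam[event_idx] == 0.0]
    if bad.size:
        raise ValueError(
            f"{cause} event(s) at age(s) {sorted(set(int(b) + age_min for b in bad))} "
            f"where the {cause} incidence curve is zero")


# ---------------------------------------------------------------------------
# public operations (single-disease)

def retro_loglik(
    records: list[CarrierRecord],
    spec: EffectSpec,
    beta,
    q: dict[str, float] | float,
    curve: IncidenceCurve,
    snp: str,
    stratify_by: str = "country",
    min_stratum_size: int = 1,
) -> float:
    """Retrospective log-likelihood at explicit (beta, per-stratum q)."""
    ds = build_analysis_data(records, snp, "breast_only", stratify_by,
                             min_stratum_size)
    engine = LikelihoodEngine(SingleDiseaseModel(spec, curve), ds)
    if isinstance(q, dict):
        qs = np.array([q[s] for s in ds.strata])
    else:
        qs = np.full(len(ds.strata), float(q))
    x = np.concatenate([np.atleast_1d(np.asarray(beta, dtype=float)),
                        _logit(qs)])
    if x.size != engine.n_params:
        raise ValueError(f"expected {engine.nb} beta parameter(s)")
    return engine.total(x)


def fit(
    records: list[CarrierRecord],
    snp: str,
    curve: IncidenceCurve,
    spec: EffectSpec | None = None,
    stratify_by: str = "country",
    min_stratum_size: int = 10,
    stratum_specific_beta: bool = False,
    robust: bool = True,
    compute_cov: bool = True,
) -> FitResult:
    """Fit the single-disease (breast cancer) retrospective-likelihood model.

    Reports per-allele (trend) or heterozygote/homozygote (2-df) hazard
    ratios with robust Wald 95% CIs, the 1-df likelihood-ratio P-trend (or
    the 2-df LRT), and jointly estimated per-stratum allele frequencies.
    """
    spec = spec or EffectSpec()
    ds = build_analysis_data(records, snp, "breast_only", stratify_by,
                             min_stratum_size)
    if not ds.is_case.any() or ds.is_case.all():
        raise ValueError("fit requires at least one affected and one "
                         "unaffected carrier")
    check_event_support(ds.end_idx[ds.is_case], curve, "breast")
    engine = LikelihoodEngine(SingleDiseaseModel(spec, curve), ds,
                              stratum_specific_beta)
    result = maximize_engine(engine, robust=robust, compute_cov=compute_cov)
    if not stratum_specific_beta:
        name = "trend_lrt" if spec.parametrization == "trend" else "genotype_2df_lrt"
        _attach_lrt(result, name, spec.n_params)
        if compute_cov:
            _attach_score_test(engine, result)
    return result


def _attach_score_test(engine: LikelihoodEngine, result: FitResult) -> None:
    """Efficient score test of beta = 0 (allele frequencies profiled)."""
    x0 = np.zeros(engine.n_params)
    x0[engine.nb:] = _logit(engine.q0())
    u = engine.grad(x0)
    hess = robust_variance.numeric_hessian(engine.total, x0)
    try:
        info_inv = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return
    ub = u[: engine.nb]
    stat = float(ub @ info_inv[: engine.nb, : engine.nb] @ ub)
    result.tests["trend_score"] = {
        "statistic": stat,
        "df": engine.nb,
        "p": float(stats.chi2.sf(max(stat, 0.0), engine.nb)),
    }


def test_age_interaction(
    records: list[CarrierRecord],
    snp: str,
    curve: IncidenceCurve,
    stratify_by: str = "country",
    min_stratum_size: int = 10,
) -> dict:
    """LRT of the genotype x age interaction (proportional-hazards check)."""
    ds = build_analysis_data(records, snp, "breast_only", stratify_by,
                             min_stratum_size)
    case_ages = ds.end_idx[ds.is_case]
    if case_ages.size and np.ptp(case_ages) == 0:
        raise ValueError("degenerate data: no age variation among cases; "
                         "interaction not identifiable")
    base = fit(records, snp, curve, EffectSpec("trend"), stratify_by,
               min_stratum_size, robust=False, compute_cov=False)
    inter = fit(records, snp, curve, EffectSpec("trend", age_interaction=True),
                stratify_by, min_stratum_size, robust=False, compute_cov=False)
    stat = max(0.0, 2.0 * (inter.loglik - base.loglik))
    return {"statistic": float(stat), "df": 1,
            "p": float(stats.chi2.sf(stat, 1)),
            "beta_age": float(inter.beta[1])}


def test_heterogeneity(
    records: list[CarrierRecord],
    snp: str,
    curve: IncidenceCurve,
    stratify_by: str = "country",
    min_stratum_size: int = 10,
) -> dict:
    """LRT of stratum-specific vs common log hazard ratios (df = K - 1)."""
    ds = build_analysis_data(records, snp, "breast_only", stratify_by,
                             min_stratum_size)
    k = len(ds.strata)
    if k < 2:
        raise ValueError("heterogeneity test needs >= 2 strata")
    common = fit(records, snp, curve, EffectSpec("trend"), stratify_by,
                 min_stratum_size, robust=False, compute_cov=False)
    specific = fit(records, snp, curve, EffectSpec("trend"), stratify_by,
                   min_stratum_size, stratum_specific_beta=True,
                   robust=False, compute_cov=False)
    stat = max(0.0, 2.0 * (specific.loglik - common.loglik))
    return {"statistic": float(stat), "df": k - 1,
            "p": float(stats.chi2.sf(stat, k - 1)), "n_strata": k}


def test_group_difference(
    fits: dict[str, FitResult] | None = None,
    records: list[CarrierRecord] | None = None,
    group_of=None,
    snp: str | None = None,
    curve: IncidenceCurve | None = None,
    param: int = 0,
    **fit_kwargs,
) -> dict:
    """Wald test of equal effects between two separately fitted groups.

    Either pass two pre-computed ``fits`` (dict name -> FitResult) or raw
    ``records`` with a ``group_of`` callable and fit arguments.  The z
    statistic uses robust SEs: z = (b1 - b2) / sqrt(se1^2 + se2^2).
    """
    if fits is None:
        if records is None or group_of is None or snp is None or curve is None:
            raise ValueError("need either fits or (records, group_of, snp, curve)")
        groups: dict[str, list[CarrierRecord]] = {}
        for rec in records:
            groups.setdefault(group_of(rec), []).append(rec)
        if len(groups) != 2:
            raise ValueError(f"group difference needs exactly 2 groups, got "
                             f"{sorted(groups)}")
        for name, grp in groups.items():
            if not grp:
                raise ValueError(f"group {name!r} is empty")
        fits = {name: fit(grp, snp, curve, **fit_kwargs)
                for name, grp in groups.items()}
    if len(fits) != 2:
        raise ValueError("group difference needs exactly 2 fits")
    (name1, f1), (name2, f2) = sorted(fits.items())
    b1, b2 = f1.beta[param], f2.beta[param]
    s1, s2 = f1.se(robust=True)[param], f2.se(robust=True)[param]
    denom = np.sqrt(s1**2 + s2**2)
    z = 0.0 if (b1 == b2) else float((b1 - b2) / denom)
    return {"groups": [name1, name2], "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z))),
            "beta": {name1: float(b1), name2: float(b2)},
            "se": {name1: float(s1), name2: float(s2)}}


def exclude_prevalent(
    records: list[CarrierRecord], window_years: int = 5
) -> list[CarrierRecord]:
    """Drop carriers diagnosed more than ``window_years`` before recruitment.

    Survival-bias sensitivity analysis: affected carriers whose breast
    cancer preceded recruitment by strictly more than the window are
    removed; unaffected carriers are always retained, and affected records
    lacking a recruitment age are retained with a warning.
    """
    kept = []
    n_norecruit = 0
    for rec in records:
        if rec.bc_age is None:
            kept.append(rec)
            continue
        if rec.recruitment_age is None:
            n_norecruit += 1
            kept.append(rec)
            continue
        if rec.recruitment_age - rec.bc_age > window_years:
            continue
        kept.append(rec)
    if n_norecruit:
        logger.warning("exclude_prevalent: %d affected record(s) lack "
                       "recruitment_age; retained", n_norecruit)
    return kept
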