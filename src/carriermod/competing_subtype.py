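"""Competing-risks and tumour-subtype extensions of the retrospective fit.

Two extensions of the single-disease model:

* **Competing risks** — breast and ovarian cancer hazards are modelled
  simultaneously as cause-specific hazards, assumed independent conditional
  on genotype.  Follow-up ends at the first cancer diagnosis; breast
  follow-up is censored at prophylactic mastectomy and ovarian follow-up at
  oophorectomy.  Each cause's baseline is constrained to its own carrier
  incidence curve, with the joint genotype-specific survival entering both
  constraints.

* **ER subtype** — the breast-cancer hazard is split by estrogen-receptor
  status of the tumour: lambda_{g,s}(t) = lam0(t) * pi_s(t) * exp(beta_s g),
  where pi_s(t) is the age-indexed fraction of carrier breast cancers of
  subtype s.  The genotype-aggregate relative risk
  r_g(t) = sum_s pi_s(t) exp(beta_s g) feeds the baseline constraint.
  Tumours with unknown ER status are assumed missing at random and
  contribute the sum over subtypes.  The subtype-difference test is a Wald
  test on beta_pos - beta_neg under the joint robust covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import CarrierRecord
from .hazard_core import (
    AGE_MAX,
    AGE_MIN,
    EffectSpec,
    GenotypeModel,
    IncidenceCurve,
    constrained_baseline_competing,
    relative_risk,
)
from .retro_inference import (
    AnalysisData,
    FitResult,
    LikelihoodEngine,
    _attach_lrt,
    build_analysis_data,
    check_event_support,
    maximize_engine,
)

logger = logging.getLogger("carriermod")

__all__ = [
    "SubtypeProportions",
    "CompetingModel",
    "SubtypeModel",
    "fit_competing",
    "fit_subtype",
]

_DOSES = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class SubtypeProportions:
    """Age-indexed split of carrier breast cancers by ER status.

    ``pi_pos[k]`` is the ER-positive fraction on age interval
    ``[age_min + k, age_min + k + 1)``; the ER-negative fraction is its
    complement.  The packaged defaults are illustrative step functions, not
    consortium pathology estimates, and should be replaced for real use.
    """

    pi_pos: np.ndarray
    age_min: int = AGE_MIN

    def __post_init__(self) -> None:
        p = np.asarray(self.pi_pos, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValueError("subtype proportions must lie in [0, 1]")
        object.__setattr__(self, "pi_pos", p)

    def on_grid(self, age_min: int = AGE_MIN, age_max: int = AGE_MAX) -> np.ndarray:
        out = np.empty(age_max - age_min)
        lo = self.age_min
        hi = self.age_min + len(self.pi_pos)
        for k, t in enumerate(range(age_min, age_max)):
            tt = min(max(t, lo), hi - 1)
            out[k] = self.pi_pos[tt - lo]
        return out

    @classmethod
    def step(cls, gene: str = "BRCA1", age_min: int = AGE_MIN,
             age_max: int = AGE_MAX) -> "SubtypeProportions":
        """Illustrative default: BRCA1 tumours mostly ER-negative, BRCA2
        mostly ER-positive, with the ER-positive share rising after 50."""
        ages = np.arange(age_min, age_max)
        if gene == "BRCA1":
            pi = np.where(ages < 50, 0.22, 0.35)
        else:
            pi = np.where(ages < 50, 0.72, 0.80)
        return cls(pi_pos=pi.astype(float), age_min=age_min)

    @classmethod
    def from_csv(cls, path, gene: str | None = None) -> "SubtypeProportions":
        """Read an age,pi_pos (optionally gene-keyed) CSV table."""
        import pandas as pd

        df = pd.read_csv(path)
        if gene is not None and "gene" in df.columns:
            df = df[df["gene"] == gene]
        if not {"age", "pi_pos"} <= set(df.columns):
            raise ValueError("subtype proportions CSV needs age,pi_pos columns")
        df = df.sort_values("age")
        return cls(pi_pos=df["pi_pos"].to_numpy(dtype=float),
                   age_min=int(df["age"].iloc[0]))


class CompetingModel:
    """Joint cause-specific model for breast and ovarian cancer."""

    mode = "competing"

    def __init__(self, spec_breast: EffectSpec, spec_ovarian: EffectSpec,
                 curve_breast: IncidenceCurve, curve_ovarian: IncidenceCurve,
                 age_min: int = AGE_MIN, age_max: int = AGE_MAX):
        self.spec_b = spec_breast
        self.spec_o = spec_ovarian
        self.curves = {"breast": curve_breast, "ovarian": curve_ovarian}
        self.age_min = age_min
        self.age_max = age_max
        self.ages = np.arange(age_min, age_max)

    @property
    def n_beta(self) -> int:
        return self.spec_b.n_params + self.spec_o.n_params

    @property
    def param_names(self) -> list[str]:
        return ([f"{nm}_breast" for nm in self.spec_b.param_names]
                + [f"{nm}_ovarian" for nm in self.spec_o.param_names])

    def split(self, beta: np.ndarray):
        nb = self.spec_b.n_params
        return beta[:nb], beta[nb:]

    def baseline(self, gm: GenotypeModel, beta: np.ndarray):
        beta_b, beta_o = self.split(beta)
        r = {"breast": relative_risk(self.spec_b, beta_b, self.ages),
             "ovarian": relative_risk(self.spec_o, beta_o, self.ages)}
        return constrained_baseline_competing(self.curves, gm, r,
                                              self.age_min, self.age_max)

    def loglik_matrix(self, ds: AnalysisData, rows: np.ndarray, bh,
                      beta: np.ndarray) -> np.ndarray:
        m = -(bh.cumhaz["breast"][:, ds.bc_idx[rows]]
              + bh.cumhaz["ovarian"][:, ds.oc_idx[rows]]).T
        st = ds.status[rows]
        for code, cause, idx in ((1, "breast", ds.bc_idx),
                                 (2, "ovarian", ds.oc_idx)):
            ev = st == code
            if ev.any():
                t = idx[rows][ev]
                m[ev] += np.log(bh.lam0[cause][t][:, None]
                                * bh.r[cause][:, t].T)
        return m


class SubtypeModel:
    """ER-subtype-specific breast-cancer model (trend per subtype).

    ``active`` marks which of (pos, neg) carry an estimable parameter: a
    subtype with zero proportion everywhere contributes no events and its
    log-HR is dropped from the parameter vector (reported absent).  With
    ``constrain_equal`` a single shared log-HR is fitted for both subtypes.
    """

    mode = "breast_only"

    def __init__(self, curve: IncidenceCurve, props: SubtypeProportions,
                 constrain_equal: bool = False,
                 age_min: int = AGE_MIN, age_max: int = AGE_MAX):
        self.curve = curve
        self.age_min = age_min
        self.age_max = age_max
        self.ages = np.arange(age_min, age_max)
        pi_pos = props.on_grid(age_min, age_max)
        self.pi = {"pos": pi_pos, "neg": 1.0 - pi_pos}
        self.constrain_equal = constrain_equal
        self.active = {s: bool(np.max(self.pi[s]) > 0) for s in ("pos", "neg")}
        if not any(self.active.values()):
            raise ValueError("subtype proportions are degenerate (all zero)")

    @property
    def subtype_names(self) -> list[str]:
        return [s for s in ("pos", "neg") if self.active[s]]

    @property
    def n_beta(self) -> int:
        if self.constrain_equal:
            return 1
        return len(self.subtype_names)

    @property
    def param_names(self) -> list[str]:
        if self.constrain_equal:
            return ["beta_shared"]
        return [f"beta_{s}" for s in self.subtype_names]

    def beta_of(self, beta: np.ndarray) -> dict[str, float]:
        if self.constrain_equal:
            return {"pos": float(beta[0]), "neg": float(beta[0])}
        out = {"pos": 0.0, "neg": 0.0}
        for name, b in zip(self.subtype_names, beta):
            out[name] = float(b)
        return out

    def aggregate_r(self, beta: np.ndarray) -> np.ndarray:
        """r_g(t) = sum_s pi_s(t) exp(beta_s g), shape (3, T)."""
        bs = self.beta_of(beta)
        r = np.zeros((3, self.ages.size))
        for s in ("pos", "neg"):
            r += self.pi[s][None, :] * np.exp(bs[s] * _DOSES)[:, None]
        return r

    def baseline(self, gm: GenotypeModel, beta: np.ndarray):
        return constrained_baseline_competing(
            {"breast": self.curve}, gm, {"breast": self.aggregate_r(beta)},
            self.age_min, self.age_max)

    def loglik_matrix(self, ds: AnalysisData, rows: np.ndarray, bh,
                      beta: np.ndarray) -> np.ndarray:
        bs = self.beta_of(beta)
        m = -bh.cumhaz["breast"][:, ds.end_idx[rows]].T
        case = ds.is_case[rows]
        er = ds.er_code[rows]
        lam0 = bh.lam0["breast"]
        for code, s in ((1, "pos"), (2, "neg")):
            ev = case & (er == code)
            if ev.any():
                t = ds.end_idx[rows][ev]
                if not self.active[s]:
                    raise ValueError(
                        f"observed ER-{s} tumour but pi_{s} is zero everywhere")
                m[ev] += (np.log(lam0[t] * self.pi[s][t])[:, None]
                          + bs[s] * _DOSES[None, :])
        ev = case & (er == 0)  # subtype missing at random: sum over subtypes
        if ev.any():
            t = ds.end_idx[rows][ev]
            dens = np.zeros((int(ev.sum()), 3))
            for s in ("pos", "neg"):
                dens += (lam0[t] * self.pi[s][t])[:, None] \
                    * np.exp(bs[s] * _DOSES)[None, :]
            m[ev] += np.log(dens)
        return m


def fit_competing(
    records: list[CarrierRecord],
    snp: str,
    curve_breast: IncidenceCurve,
    curve_ovarian: IncidenceCurve | None = None,
    spec_breast: EffectSpec | None = None,
    spec_ovarian: EffectSpec | None = None,
    stratify_by: str = "country",
    min_stratum_size: int = 10,
    robust: bool = True,
    compute_cov: bool = True,
) -> FitResult:
    """Joint retrospective-likelihood fit of breast and ovarian log-HRs.

    Requires both diseases' incidence curves; the per-disease censoring of
    the competing follow-up (mastectomy for breast, oophorectomy for
    ovarian) is honoured.  Reports cause-specific HRs with robust CIs and
    the joint LRT against all effects zero.
    """
    if curve_ovarian is None:
        raise ValueError("competing-risks fit requires an ovarian incidence "
                         "curve")
    spec_breast = spec_breast or EffectSpec()
    spec_ovarian = spec_ovarian or EffectSpec()
    ds = build_analysis_data(records, snp, "competing", stratify_by,
                             min_stratum_size)
    check_event_support(ds.bc_idx[ds.status == 1], curve_breast, "breast")
    check_event_support(ds.oc_idx[ds.status == 2], curve_ovarian, "ovarian")
    model = CompetingModel(spec_breast, spec_ovarian, curve_breast,
                           curve_ovarian)
    engine = LikelihoodEngine(model, ds)
    result = maximize_engine(engine, robust=robust, compute_cov=compute_cov)
    _attach_lrt(result, "joint_lrt", model.n_beta)
    counts = {}
    for code, label in ((0, "unaffected"), (1, "breast"), (2, "ovarian")):
        mask = ds.status == code
        counts[label] = [int((ds.dose[mask] == g).sum()) for g in (0, 1, 2)]
    result.genotype_counts = counts
    return result


def fit_subtype(
    records: list[CarrierRecord],
    snp: str,
    curve: IncidenceCurve,
    props: SubtypeProportions | None = None,
    gene: str | None = None,
    constrain_equal: bool = False,
    stratify_by: str = "country",
    min_stratum_size: int = 10,
    robust: bool = True,
    compute_cov: bool = True,
) -> FitResult:
    """Fit ER-positive and ER-negative breast-cancer log-HRs simultaneously.

    Affected carriers with unknown ER status stay in the analysis under a
    missing-at-random assumption.  The returned result carries the
    subtype-difference Wald test (``subtype_difference``) on
    beta_pos - beta_neg using the joint robust covariance.
    """
    if props is None:
        props = SubtypeProportions.step(gene or records[0].gene)
    ds = build_analysis_data(records, snp, "breast_only", stratify_by,
                             min_stratum_size)
    check_event_support(ds.end_idx[ds.is_case], curve, "breast")
    model = SubtypeModel(curve, props, constrain_equal=constrain_equal)
    engine = LikelihoodEngine(model, ds)
    result = maximize_engine(engine, robust=robust, compute_cov=compute_cov)
    _attach_lrt(result, "subtype_lrt", model.n_beta)
    if (not constrain_equal and len(model.subtype_names) == 2
            and result.cov_robust is not None):
        c = np.zeros(result.estimates.size)
        c[0], c[1] = 1.0, -1.0  # beta_pos - beta_neg
        var = float(c @ result.cov_robust @ c)
        diff = float(result.beta[0] - result.beta[1])
        z = diff / np.sqrt(var) if var > 0 else np.nan
        result.tests["subtype_difference"] = {
            "diff": diff, "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        }
    counts = {}
    er_label = {0: "er_missing", 1: "er_pos", 2: "er_neg"}
    counts["unaffected"] = [int((ds.dose[~ds.is_case] == g).sum())
                            for g in (0, 1, 2)]
    for code, label in er_label.items():
        mask = ds.is_case & (ds.er_code == code)
        counts[label] = [int((ds.dose[mask] == g).sum()) for g in (0, 1, 2)]
    result.genotype_counts = counts
    return result
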