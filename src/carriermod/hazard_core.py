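"""Genotype model, incidence-constrained baseline hazards, and per-genotype
phenotype likelihoods.

This module is the mathematical heart of the package.  A modifier SNP is
assumed to act multiplicatively on a carrier's cause-specific cancer hazard:
a carrier of genotype ``g`` (minor-allele dose 0, 1 or 2) has hazard

    lambda_g(t) = lambda_0(t) * r_g(t)

at integer age ``t``, where ``r_g(t)`` is the genotype relative risk
(per-allele/trend or free 2-df parametrization, optionally age-varying) and
``lambda_0(t)`` is a baseline hazard.  Because carrier cohorts are
ascertained through clinics, the baseline is not estimated freely: it is
constrained so that the *genotype-averaged* hazard among still-unaffected
carriers reproduces an externally supplied carrier incidence (penetrance)
curve ``lambda*(t)`` at every age.  With HWE genotype prior ``p_g`` and
genotype-specific survival ``S_g(t)`` this gives the forward recursion

    lambda_0(t) = lambda*(t) * sum_g p_g S_g(t) / sum_g p_g S_g(t) r_g(t),

computed age by age from ``S_g(a_min) = 1``.  The same recursion extends to
competing causes (breast and ovarian cancer), with the joint survival
``S_g(t) = exp(-sum_d cumhaz_{d,g}(t))`` entering both causes' constraints.

Hazards are piecewise constant on yearly intervals ``[t, t+1)``; the default
age grid is 18-80 with hazard zero outside.  An affected individual's
likelihood factor uses the event density ``S_g(t) * lambda_g(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "GenotypeModel",
    "IncidenceCurve",
    "EffectSpec",
    "BaselineHazard",
    "hwe_probs",
    "relative_risk",
    "constrained_baseline",
    "constrained_baseline_competing",
    "phenotype_loglik_vector",
]

AGE_MIN = 18
AGE_MAX = 80  #: follow-up beyond this age is truncated; hazard 0 outside

_DOSES = np.array([0.0, 1.0, 2.0])


def hwe_probs(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {q}")
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2])


@dataclass(frozen=True)
class GenotypeModel:
    """HWE genotype prior at minor-allele frequency ``q`` (one stratum)."""

    q: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"allele frequency must lie in [0, 1], got {self.q}")

    @property
    def probs(self) -> np.ndarray:
        return hwe_probs(self.q)


@dataclass(frozen=True)
class IncidenceCurve:
    """Yearly carrier-average hazard for one disease/gene (one cohort band).

    ``hazard[k]`` applies on the age interval ``[age_min + k, age_min + k + 1)``.
    """

    disease: str  # "breast" | "ovarian"
    gene: str  # "BRCA1" | "BRCA2"
    hazard: np.ndarray
    age_min: int = AGE_MIN
    cohort_band: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.hazard, dtype=float)
        if h.ndim != 1 or h.size == 0:
            raise ValueError("hazard must be a non-empty 1-d array")
        if not np.all(np.isfinite(h)) or np.any(h < 0):
            raise ValueError(
                f"incidence hazards must be finite and non-negative "
                f"({self.disease}/{self.gene}/{self.cohort_band or '-'})"
            )
        object.__setattr__(self, "hazard", h)

    @property
    def age_max(self) -> int:
        return self.age_min + len(self.hazard)

    def on_grid(self, age_min: int = AGE_MIN, age_max: int = AGE_MAX) -> np.ndarray:
        """Hazard resampled onto ``[age_min, age_max)``; zero outside support."""
        out = np.zeros(age_max - age_min)
        lo = max(age_min, self.age_min)
        hi = min(age_max, self.age_max)
        if hi > lo:
            out[lo - age_min : hi - age_min] = self.hazard[
                lo - self.age_min : hi - self.age_min
            ]
        return out


@dataclass(frozen=True)
class EffectSpec:
    """Parametrization of the genotype relative risk.

    parametrization
        ``"trend"``: log r_g = beta * g (per-allele, multiplicative).
        ``"genotype2df"``: log r_1 = beta_het, log r_2 = beta_hom.
    age_interaction
        trend only: log r_g(t) = (beta0 + beta1 * (t - 40) / 10) * g, i.e. the
        per-allele log-HR drifts linearly with age, centred at 40.
    """

    parametrization: str = "trend"
    age_interaction: bool = False
    age_center: float = 40.0
    age_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.parametrization not in ("trend", "genotype2df"):
            raise ValueError(f"unknown parametrization {self.parametrization!r}")
        if self.age_interaction and self.parametrization != "trend":
            raise ValueError("age interaction is defined for the trend model only")

    @property
    def n_params(self) -> int:
        base = 1 if self.parametrization == "trend" else 2
        return base + (1 if self.age_interaction else 0)

    @property
    def param_names(self) -> list[str]:
        if self.parametrization == "trend":
            names = ["beta"]
            if self.age_interaction:
                names.append("beta_age")
            return names
        return ["beta_het", "beta_hom"]


def relative_risk(
    spec: EffectSpec,
    beta: np.ndarray | list[float] | float,
    ages: np.ndarray | None = None,
) -> np.ndarray:
    """Genotype relative risks r_g(t) on the age grid.

    Returns an array of shape (3, n_ages): one row per genotype dose.  With
    no age interaction the rows are constant in age.
    """
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX)
    ages = np.asarray(ages, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size != spec.n_params:
        raise ValueError(
            f"expected {spec.n_params} parameter(s) for {spec.parametrization}"
            f"{' + age interaction' if spec.age_interaction else ''}, got {beta.size}"
        )
    if spec.parametrization == "trend":
        b_t = beta[0]
        if spec.age_interaction:
            b_t = beta[0] + beta[1] * (ages - spec.age_center) / spec.age_scale
        log_r = _DOSES[:, None] * np.broadcast_to(b_t, ages.shape)[None, :]
    else:
        per_g = np.array([0.0, beta[0], beta[1]])
        log_r = np.broadcast_to(per_g[:, None], (3, ages.size)).copy()
    return np.exp(log_r)


@dataclass
class BaselineHazard:
    """Constrained baseline hazard(s) with cached genotype-specific quantities.

    For each cause ``d`` the arrays ``lam0[d]`` (length T) and ``r[d]``
    (3 x T) define genotype hazards on ``ages``; ``cumhaz[d]`` (3 x (T+1))
    holds the cumulative genotype hazard up to the *start* of each interval,
    so ``cumhaz[d][g, k] = sum_{j<k} lam0[d][j] * r[d][g, j]``.
    """

    ages: np.ndarray
    lam0: dict[str, np.ndarray]
    r: dict[str, np.ndarray]
    cumhaz: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cumhaz:
            for d, lam in self.lam0.items():
                gh = lam[None, :] * self.r[d]
                cum = np.zeros((3, len(self.ages) + 1))
                np.cumsum(gh, axis=1, out=cum[:, 1:])
                self.cumhaz[d] = cum

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    def age_index(self, age: float) -> int:
        idx = int(age) - self.age_min
        if idx < 0 or idx > len(self.ages):
            raise ValueError(f"age {age} outside baseline grid "
                             f"[{self.ages[0]}, {self.ages[-1] + 1}]")
        return idx

    def survival(self, cause: str, g: int, age: float) -> float:
        """S_g(age): probability cause-``cause``-free to the start of ``age``."""
        return float(np.exp(-self.cumhaz[cause][g, self.age_index(age)]))

    def to_frame(self):
        """Long-format table of the baseline, for debugging/CSV dumps."""
        import pandas as pd

        rows = []
        for d, lam in self.lam0.items():
            for k, t in enumerate(self.ages):
                rows.append(
                    {"disease": d, "age": int(t), "lam0": lam[k],
                     "r0": self.r[d][0, k], "r1": self.r[d][1, k],
                     "r2": self.r[d][2, k]}
                )
        return pd.DataFrame(rows)


def _forward_baseline(
    lam_stars: list[np.ndarray],
    probs: np.ndarray,
    r_list: list[np.ndarray],
) -> list[np.ndarray]:
    """Joint forward recursion constraining each cause's marginal hazard.

    At each age the genotype-averaged cause-specific hazard among survivors
    (of *all* causes) is forced to equal the supplied curve for that cause.
    """
    n_ages = lam_stars[0].size
    lam0s = [np.zeros(n_ages) for _ in lam_stars]
    surv = np.ones(3)  # joint genotype-specific survival to start of interval
    for k in range(n_ages):
        w = probs * surv
        num = w.sum()
        if num <= 0.0 or not np.isfinite(num):
            raise ValueError(
                "degenerate hazard: survival mass extinguished before end of grid"
            )
        tot = np.zeros(3)
        for lam_star, lam0, r in zip(lam_stars, lam0s, r_list):
            den = float(w @ r[:, k])
            if lam_star[k] > 0 and den <= 0.0:
                raise ValueError("degenerate hazard: zero risk mass with "
                                 "positive target incidence")
            lam0[k] = 0.0 if lam_star[k] == 0.0 else lam_star[k] * num / den
            tot += lam0[k] * r[:, k]
        surv = surv * np.exp(-tot)
    return lam0s


def constrained_baseline(
    curve: IncidenceCurve,
    gm: GenotypeModel,
    spec: EffectSpec,
    beta,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> BaselineHazard:
    """Single-disease baseline constrained to the supplied incidence curve.

    The returned baseline satisfies, at every age t,

        sum_g p_g S_g(t) lam0(t) r_g(t) / sum_g p_g S_g(t) = lambda*(t)

    to numerical precision (the module's defining identity).
    """
    ages = np.arange(age_min, age_max)
    r = relative_risk(spec, beta, ages)
    lam_star = curve.on_grid(age_min, age_max)
    (lam0,) = _forward_baseline([lam_star], gm.probs, [r])
    return BaselineHazard(ages=ages, lam0={curve.disease: lam0}, r={curve.disease: r})


def constrained_baseline_competing(
    curves: dict[str, IncidenceCurve],
    gm: GenotypeModel,
    r_by_cause: dict[str, np.ndarray],
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> BaselineHazard:
    """Jointly constrained baselines for several competing causes.

    ``r_by_cause`` maps cause name to a (3, n_ages) relative-risk array
    (allowing the caller to build cause- or subtype-aggregated risks).  The
    joint genotype survival over all causes enters every cause's constraint.
    """
    ages = np.arange(age_min, age_max)
    causes = list(curves)
    lam_stars = [curves[d].on_grid(age_min, age_max) for d in causes]
    r_list = [np.asarray(r_by_cause[d], dtype=float) for d in causes]
    for d, r in zip(causes, r_list):
        if r.shape != (3, ages.size):
            raise ValueError(f"relative-risk array for {d} must be 3 x {ages.size}")
    lam0s = _forward_baseline(lam_stars, gm.probs, r_list)
    return BaselineHazard(
        ages=ages,
        lam0=dict(zip(causes, lam0s)),
        r=dict(zip(causes, r_list)),
    )


def phenotype_loglik_vector(fu, bh: BaselineHazard, mode: str = "breast_only") -> np.ndarray:
    """Log-likelihood of one individual's phenotype, per genotype.

    ``fu`` is a follow-up record (``end_age``, ``status``, and for the
    competing mode per-disease end ages ``bc_end`` / ``oc_end``).  Unaffected
    individuals contribute log S_g(end); an individual affected at age t
    contributes log S_g(t) + log(lam0(t) r_g(t)) with the cause-specific
    hazard of the observed disease.  Returns the length-3 vector indexed by
    genotype dose.
    """
    out = np.zeros(3)
    if mode == "breast_only":
        idx = bh.age_index(fu.end_age)
        out -= bh.cumhaz["breast"][:, idx]
        if fu.status == "breast":
            if idx >= len(bh.ages):
                raise ValueError("event age outside hazard grid")
            out += np.log(bh.lam0["breast"][idx] * bh.r["breast"][:, idx])
    elif mode == "competing":
        idx_b = bh.age_index(fu.bc_end)
        idx_o = bh.age_index(fu.oc_end)
        out -= bh.cumhaz["breast"][:, idx_b]
        out -= bh.cumhaz["ovarian"][:, idx_o]
        if fu.status in ("breast", "ovarian"):
            d = fu.status
            idx = idx_b if d == "breast" else idx_o
            if idx >= len(bh.ages):
                raise ValueError("event age outside hazard grid")
            out += np.log(bh.lam0[d][idx] * bh.r[d][:, idx])
    else:
        raise ValueError(f"unknown follow-up mode {mode!r}")
    return out
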