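"""Genotyping quality control for carrier genotype matrices.

Implements the QC pipeline used for consortium iPLEX genotyping rounds:
per-sample missingness exclusion, per-study per-SNP call-rate checks,
duplicate-sample concordance, cross-centre test-plate consistency,
per-study Hardy-Weinberg tests on unrelated subjects, and duplicate-subject
detection from phenotype keys or genotype identity.

Genotype matrices are pandas DataFrames (samples x SNPs) with values in
{0, 1, 2} and NaN for a failed call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("carriermod")

#: HWE p-value below which a (study, SNP) is excluded outright
HWE_EXCLUDE_P = 0.005
#: HWE p-values in [HWE_EXCLUDE_P, HWE_REVIEW_P) are flagged for review
HWE_REVIEW_P = 0.05


@dataclass
class QCReport:
    """Aggregated QC outcome with exclusion lists and reason codes."""

    sample_missing: pd.Series | None = None  # per-sample missing fraction
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    study_call_rate: pd.DataFrame | None = None  # (study, snp) -> rate, pass
    failed_study_snps: list[tuple[str, str, str]] = field(default_factory=list)
    duplicate_concordance: dict[str, float] = field(default_factory=dict)
    hwe: pd.DataFrame | None = None  # per (study, snp): chi2, p, flag
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded_samples": [list(t) for t in self.excluded_samples],
            "failed_study_snps": [list(t) for t in self.failed_study_snps],
            "duplicate_concordance": self.duplicate_concordance,
            "hwe": (self.hwe.to_dict(orient="records")
                    if self.hwe is not None else []),
            "warnings": list(self.warnings),
        }


def missingness_cutoff(n_snps_typed: int, fail_fraction: float = 0.20) -> int:
    """Missing-call count at or above which a sample is excluded.

    The rule is an explicit count: ``max(1, round(fail_fraction * n))``, so
    that with 26 SNPs typed the cutoff is 5 missing calls ("five or more").
    """
    if n_snps_typed <= 0:
        raise ValueError("n_snps_typed must be positive")
    return max(1, int(round(fail_fraction * n_snps_typed)))


def sample_missingness_filter(
    genotypes: pd.DataFrame,
    n_snps_typed: int | None = None,
    fail_fraction: float = 0.20,
) -> list[str]:
    """Samples to exclude for failing too many of the SNPs typed.

    ``n_snps_typed`` defaults to the matrix width (the SNPs in this round).
    """
    if n_snps_typed is None:
        n_snps_typed = genotypes.shape[1]
    cutoff = missingness_cutoff(n_snps_typed, fail_fraction)
    n_missing = genotypes.isna().sum(axis=1)
    return list(n_missing.index[n_missing >= cutoff])


def study_call_rate_check(
    genotypes: pd.DataFrame,
    study_of: pd.Series,
    min_rate: float = 0.95,
) -> pd.DataFrame:
    """Per-(study, SNP) call rates with a strict ``rate > min_rate`` rule.

    Apply *after* sample-level exclusions.  An empty study fails with
    reason ``no data``.  Returns a DataFrame with columns study, snp,
    n_called, n_total, call_rate, passed, reason.
    """
    rows = []
    for study, idx in genotypes.groupby(study_of).groups.items():
        sub = genotypes.loc[idx]
        for snp in genotypes.columns:
            n_total = len(sub)
            n_called = int(sub[snp].notna().sum())
            if n_total == 0:
                rows.append((study, snp, 0, 0, float("nan"), False, "no data"))
                continue
            rate = n_called / n_total
            ok = rate > min_rate
            rows.append((study, snp, n_called, n_total, rate, ok,
                         "" if ok else "low call rate"))
    return pd.DataFrame(
        rows, columns=["study", "snp", "n_called", "n_total", "call_rate",
                       "passed", "reason"],
    )


def duplicate_concordance_check(
    pairs: list[tuple[pd.Series, pd.Series]],
    min_concord: float = 0.98,
) -> tuple[bool, float, list[str]]:
    """Concordance of duplicate-sample genotype pairs within one study.

    Each pair is compared at SNPs where both calls are non-missing; the
    pass rule is ``concordant / compared >= min_concord``.  With no
    comparable pairs the check passes with a warning (nothing to assess).
    Returns (passed, concordance, warnings).
    """
    warnings: list[str] = []
    n_comp = 0
    n_conc = 0
    for a, b in pairs:
        both = a.notna() & b.notna()
        n_comp += int(both.sum())
        n_conc += int((a[both] == b[both]).sum())
    if n_comp == 0:
        warnings.append("no comparable duplicate calls; concordance not assessed")
        return True, float("nan"), warnings
    conc = n_conc / n_comp
    return conc >= min_concord, conc, warnings


def cross_centre_plate_check(
    plate_calls: dict[str, pd.DataFrame],
    max_inconsistent: int = 1,
) -> pd.DataFrame:
    """Consistency of shared test-plate samples across genotyping centres.

    ``plate_calls`` maps centre name to a samples x SNPs matrix of the
    shared test plate.  For each SNP and each pair of centres, samples with
    discordant non-missing calls are counted; a centre pair fails a SNP iff
    the count exceeds ``max_inconsistent`` ("more than one sample").
    """
    centres = sorted(plate_calls)
    rows = []
    for c1, c2 in combinations(centres, 2):
        a, b = plate_calls[c1], plate_calls[c2]
        shared_samples = a.index.intersection(b.index)
        shared_snps = a.columns.intersection(b.columns)
        for snp in shared_snps:
            x = a.loc[shared_samples, snp]
            y = b.loc[shared_samples, snp]
            both = x.notna() & y.notna()
            n_disc = int((x[both] != y[both]).sum())
            rows.append((snp, c1, c2, n_disc, n_disc <= max_inconsistent))
    return pd.DataFrame(
        rows, columns=["snp", "centre_a", "centre_b", "n_discordant", "passed"]
    )


def hwe_test(n0: int, n1: int, n2: int, method: str = "chi2") -> tuple[float, float]:
    """Test deviation from Hardy-Weinberg equilibrium for one SNP/study.

    ``(n0, n1, n2)`` are genotype counts (major hom, het, minor hom).  The
    default is the 1-df asymptotic chi-square against HWE-expected counts at
    the MLE allele frequency; ``method="exact"`` uses the conditional exact
    test (sum of heterozygote-count probabilities no larger than the
    observed one's).  Monomorphic counts return (0.0, 1.0).
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no genotypes")
    q = (n1 + 2 * n2) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    if method == "chi2":
        expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        chi2 = float((((np.array([n0, n1, n2]) - expected) ** 2) / expected).sum())
        return chi2, float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n0, n1, n2)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """Exact HWE test conditional on allele counts (Wigginton-style)."""
    n = n0 + n1 + n2
    n_minor = n1 + 2 * n2
    n_minor = min(n_minor, 2 * n - n_minor)
    # heterozygote counts share the parity of the minor-allele count
    hets = range(n_minor % 2, n_minor + 1, 2)
    logprobs = {}
    for h in hets:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        lp = (math.lgamma(n + 1) - math.lgamma(hom_maj + 1)
              - math.lgamma(h + 1) - math.lgamma(hom_min + 1)
              + h * math.log(2.0)
              + math.lgamma(n_minor + 1) + math.lgamma(2 * n - n_minor + 1)
              - math.lgamma(2 * n + 1))
        logprobs[h] = lp
    mx = max(logprobs.values())
    probs = {h: math.exp(lp - mx) for h, lp in logprobs.items()}
    z = sum(probs.values())
    obs = min(n1, max(logprobs))
    p_obs = probs.get(n1, 0.0)
    p = sum(pr for pr in probs.values() if pr <= p_obs * (1 + 1e-12)) / z
    return float("nan"), min(1.0, p)


def hwe_by_study(
    genotypes: pd.DataFrame,
    study_of: pd.Series,
    family_of: pd.Series | None = None,
    individual_ids: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-(study, SNP) HWE chi-square on unrelated subjects.

    Unrelatedness convention: one member per ``family_id``, the lowest
    ``individual_id`` (deterministic).  Studies with p < 0.005 are marked
    ``exclude``; p in [0.005, 0.05) are flagged ``review`` (in lieu of
    cluster-plot inspection) and a warning is logged.
    """
    idx = genotypes.index
    if family_of is not None:
        ids = individual_ids if individual_ids is not None else pd.Series(
            idx, index=idx)
        pick = (pd.DataFrame({"fam": family_of, "iid": ids})
                .sort_values("iid").groupby("fam", sort=False).head(1).index)
        genotypes = genotypes.loc[genotypes.index.intersection(pick)]
        study_of = study_of.loc[genotypes.index]
    rows = []
    for study, sub_idx in genotypes.groupby(study_of).groups.items():
        sub = genotypes.loc[sub_idx]
        for snp in genotypes.columns:
            counts = sub[snp].value_counts()
            n0, n1, n2 = (int(counts.get(float(g), 0) + counts.get(g, 0))
                          for g in (0, 1, 2))
            if n0 + n1 + n2 == 0:
                continue
            chi2, p = hwe_test(n0, n1, n2)
            flag = "ok"
            if p < HWE_EXCLUDE_P:
                flag = "exclude"
            elif p < HWE_REVIEW_P:
                flag = "review"
                logger.warning(
                    "HWE p=%.4g for %s in study %s: flagged for cluster-plot "
                    "review", p, snp, study)
            rows.append((study, snp, n0, n1, n2, chi2, p, flag))
    return pd.DataFrame(
        rows, columns=["study", "snp", "n0", "n1", "n2", "chi2", "p", "flag"]
    )


def find_potential_duplicates(
    records,
    genotypes: pd.DataFrame | None = None,
    min_shared_snps: int = 26,
    min_identity: float = 0.95,
) -> list[tuple[str, str, str]]:
    """Candidate duplicate subjects across studies.

    A pair is flagged when (a) birth year, mutation description and all
    recorded event/censoring ages match exactly, or (b) their non-missing
    genotype identity is at least ``min_identity`` over at least
    ``min_shared_snps`` shared calls.  Returns (id_a, id_b, rule) tuples.
    """
    flagged: list[tuple[str, str, str]] = []

    def pheno_key(rec):
        mut = rec.mutation if rec.mutation else f"class:{rec.mutation_class}"
        return (rec.birth_year, rec.gene, mut, rec.age_last_obs, rec.bc_age,
                rec.oc_age, rec.mastectomy_age, rec.oophorectomy_age)

    by_key: dict[tuple, list[str]] = {}
    for rec in records:
        by_key.setdefault(pheno_key(rec), []).append(rec.individual_id)
    for ids in by_key.values():
        for a, b in combinations(sorted(ids), 2):
            flagged.append((a, b, "phenotype"))

    if genotypes is not None and len(genotypes) > 1:
        g = genotypes.to_numpy(dtype=float)
        ids = list(genotypes.index)
        seen = {(a, b) for a, b, _ in flagged}
        for i, j in combinations(range(len(ids)), 2):
            both = ~(np.isnan(g[i]) | np.isnan(g[j]))
            n_shared = int(both.sum())
            if n_shared < min_shared_snps:
                continue
            identity = float((g[i][both] == g[j][both]).mean())
            pair = tuple(sorted((ids[i], ids[j])))
            if identity >= min_identity and pair not in seen:
                flagged.append((pair[0], pair[1], "genotype"))
    return flagged


def run_qc(
    genotypes: pd.DataFrame,
    study_of: pd.Series,
    family_of: pd.Series | None = None,
    duplicate_pairs: dict[str, list[tuple[pd.Series, pd.Series]]] | None = None,
    fail_fraction: float = 0.20,
    min_call_rate: float = 0.95,
    min_concord: float = 0.98,
) -> QCReport:
    """Run the full sample/study QC pipeline and assemble a QCReport."""
    report = QCReport()
    report.sample_missing = genotypes.isna().mean(axis=1)
    bad = sample_missingness_filter(genotypes, fail_fraction=fail_fraction)
    report.excluded_samples = [(s, "sample_missingness") for s in bad]
    kept = genotypes.drop(index=bad)
    kept_study = study_of.loc[kept.index]
    report.study_call_rate = study_call_rate_check(kept, kept_study,
                                                  min_rate=min_call_rate)
    report.failed_study_snps = [
        (r.study, r.snp, r.reason)
        for r in report.study_call_rate.itertuples()
        if not r.passed
    ]
    if duplicate_pairs:
        for study, pairs in duplicate_pairs.items():
            ok, conc, warns = duplicate_concordance_check(pairs, min_concord)
            report.duplicate_concordance[study] = conc
            report.warnings.extend(warns)
            if not ok:
                report.failed_study_snps.extend(
                    (study, snp, "low duplicate concordance")
                    for snp in genotypes.columns
                )
    report.hwe = hwe_by_study(kept, kept_study, family_of)
    if report.hwe is not None and len(report.hwe):
        for r in report.hwe.itertuples():
            if r.flag == "exclude":
                report.failed_study_snps.append((r.study, r.snp, "HWE failure"))
    return report
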