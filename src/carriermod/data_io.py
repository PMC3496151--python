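"""Carrier tables, incidence curves, eligibility and censoring rules.

The on-disk carrier table is plain TSV with a versioned comment header;
missing values are empty fields.  One row per mutation carrier, one column
per SNP holding the minor-allele dose (0/1/2, empty when untyped).

Censoring conventions (ages are integer years, events on ``[t, t+1)``):

* breast-only analysis — follow-up ends at the first of breast cancer
  diagnosis, ovarian cancer diagnosis, bilateral prophylactic mastectomy,
  or last observation; only a first breast cancer counts as affected, and
  carriers censored at ovarian diagnosis are treated as unaffected.
* competing-risks analysis — follow-up ends at the first breast or ovarian
  cancer diagnosis, with that status; no follow-up after a first cancer.
  Breast follow-up is additionally censored at mastectomy and ovarian
  follow-up at oophorectomy.

Ties among candidate end ages resolve in the fixed priority
breast > ovarian > mastectomy > last observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hazard_core import IncidenceCurve

logger = logging.getLogger("carriermod")

CARRIER_TABLE_VERSION = "carriermod-carrier-table-v1"

#: mandatory columns of a carrier table (besides the per-SNP dose columns)
MANDATORY_COLUMNS = [
    "individual_id",
    "family_id",
    "study_id",
    "country",
    "gene",
    "birth_year",
    "age_last_obs",
]

OPTIONAL_COLUMNS = [
    "mutation_class",
    "mutation",
    "bc_age",
    "oc_age",
    "mastectomy_age",
    "oophorectomy_age",
    "recruitment_age",
    "er_status",
    "double_carrier",
]

GENES = ("BRCA1", "BRCA2")
MUTATION_CLASSES = ("class1", "class2", "other", "unknown")
ER_STATUSES = ("pos", "neg")


@dataclass
class CarrierRecord:
    """One mutation carrier: identifiers, censoring ages and genotypes."""

    individual_id: str
    family_id: str
    study_id: str
    country: str
    gene: str
    birth_year: int
    age_last_obs: int
    mutation_class: str = "unknown"
    mutation: str = ""  # free-text mutation description, for duplicate checks
    bc_age: int | None = None
    oc_age: int | None = None
    mastectomy_age: int | None = None
    oophorectomy_age: int | None = None
    recruitment_age: int | None = None
    er_status: str | None = None  # "pos"/"neg", None = missing
    double_carrier: bool = False
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems = []
        if self.gene not in GENES:
            problems.append(f"unknown gene {self.gene!r}")
        if self.mutation_class not in MUTATION_CLASSES:
            problems.append(f"unknown mutation_class {self.mutation_class!r}")
        if self.age_last_obs is None or self.age_last_obs < 0:
            problems.append("age_last_obs missing or negative")
        else:
            for name in ("bc_age", "oc_age", "mastectomy_age", "oophorectomy_age"):
                age = getattr(self, name)
                if age is not None and age > self.age_last_obs:
                    problems.append(f"event after censoring ({name}={age} > "
                                    f"age_last_obs={self.age_last_obs})")
        for name in ("bc_age", "oc_age", "mastectomy_age", "oophorectomy_age",
                     "recruitment_age"):
            age = getattr(self, name)
            if age is not None and age < 0:
                problems.append(f"negative {name}")
        if self.recruitment_age is not None and self.recruitment_age < 18:
            problems.append("recruitment before age 18 (ineligible)")
        if self.er_status is not None:
            if self.er_status not in ER_STATUSES:
                problems.append(f"unknown er_status {self.er_status!r}")
            if self.bc_age is None:
                problems.append("er_status recorded without a breast cancer")
        for snp, dose in self.genotypes.items():
            if dose is not None and dose not in (0, 1, 2):
                problems.append(f"genotype dose for {snp} not in {{0,1,2}}")
        return problems


@dataclass(frozen=True)
class FollowUp:
    """Derived censoring summary of one carrier.

    ``end_age``/``status`` drive the breast-only likelihood; ``bc_end`` and
    ``oc_end`` are the per-disease end ages of the competing-risks model.
    """

    end_age: int
    status: str  # "unaffected" | "breast" | "ovarian"
    bc_end: int
    oc_end: int


def derive_followup(record: CarrierRecord, mode: str = "breast_only") -> FollowUp:
    """Apply the censoring rules to one record.

    Deterministic and total on valid records; raises ``ValueError`` when no
    candidate end age is available or the mode is unknown.
    """
    bc, oc = record.bc_age, record.oc_age
    mast, ooph = record.mastectomy_age, record.oophorectomy_age
    last = record.age_last_obs
    if mode == "breast_only":
        candidates = [(bc, "breast"), (oc, "unaffected"),
                      (mast, "unaffected"), (last, "unaffected")]
        candidates = [(a, s) for a, s in candidates if a is not None]
        if not candidates:
            raise ValueError(f"record {record.individual_id}: no end age available")
        # stable min: ties resolve by listed priority (bc > oc > mast > last)
        end_age, status = min(candidates, key=lambda t: t[0])
        return FollowUp(end_age=end_age, status=status, bc_end=end_age, oc_end=end_age)
    if mode == "competing":
        if last is None and bc is None and oc is None:
            raise ValueError(f"record {record.individual_id}: no end age available")
        # an event only counts if not pre-empted by the matching surgery
        eff_bc = bc if bc is not None and (mast is None or bc <= mast) else None
        eff_oc = oc if oc is not None and (ooph is None or oc <= ooph) else None
        events = [(a, s) for a, s in ((eff_bc, "breast"), (eff_oc, "ovarian"))
                  if a is not None]
        if events:
            end_age, status = min(events, key=lambda t: t[0])
        else:
            end_age, status = last, "unaffected"
        bc_end = min(end_age if mast is None else min(end_age, mast), end_age)
        oc_end = min(end_age if ooph is None else min(end_age, ooph), end_age)
        return FollowUp(end_age=end_age, status=status, bc_end=bc_end, oc_end=oc_end)
    raise ValueError(f"unknown follow-up mode {mode!r}")


# ---------------------------------------------------------------------------
# carrier-table I/O

_INT_FIELDS = ("birth_year", "age_last_obs", "bc_age", "oc_age",
               "mastectomy_age", "oophorectomy_age", "recruitment_age")


def _parse_opt_int(value, column: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unparsable {column} value {value!r}") from None
    if f != int(f):
        raise ValueError(f"non-integer {column} value {value!r}")
    return int(f)


def load_carrier_table(
    path: str | Path, snp_names: list[str]
) -> tuple[list[CarrierRecord], list[tuple[int, str]]]:
    """Read a carrier TSV; return (valid records, [(line_number, reason)]).

    Unknown columns are ignored.  Rows violating record invariants are
    rejected with a row-level diagnostic; a missing mandatory column is a
    format error naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"carrier table {path}: missing mandatory column "
                             f"{col!r}")
    missing_snps = [s for s in snp_names if s not in df.columns]
    if missing_snps:
        raise ValueError(f"carrier table {path}: missing SNP column(s) "
                         f"{', '.join(missing_snps)}")
    records: list[CarrierRecord] = []
    rejects: list[tuple[int, str]] = []
    # line numbers: 1-based, counting the header (comment lines excluded by
    # pandas, so recompute offset from the raw file)
    with open(path) as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    header_line = n_comment + 1
    for i, row in df.iterrows():
        line_no = header_line + 1 + int(i)
        try:
            kwargs: dict = {
                "individual_id": row["individual_id"],
                "family_id": row["family_id"],
                "study_id": row["study_id"],
                "country": row["country"],
                "gene": row["gene"],
            }
            for name in _INT_FIELDS:
                val = _parse_opt_int(row.get(name, ""), name)
                if name in ("birth_year", "age_last_obs"):
                    if val is None:
                        raise ValueError(f"missing {name}")
                    kwargs[name] = val
                else:
                    kwargs[name] = val
            kwargs["mutation_class"] = row.get("mutation_class", "") or "unknown"
            kwargs["mutation"] = row.get("mutation", "")
            er = row.get("er_status", "")
            kwargs["er_status"] = er if er else None
            dc = str(row.get("double_carrier", "")).strip().lower()
            kwargs["double_carrier"] = dc in ("1", "true", "yes")
            kwargs["genotypes"] = {
                s: _parse_opt_int(row[s], s) for s in snp_names
            }
            rec = CarrierRecord(**kwargs)
        except ValueError as exc:
            rejects.append((line_no, str(exc)))
            continue
        problems = rec.validate()
        if problems:
            rejects.append((line_no, "; ".join(problems)))
        else:
            records.append(rec)
    for line_no, reason in rejects:
        logger.warning("carrier table %s line %d rejected: %s", path, line_no,
                       reason)
    return records, rejects


def read_carrier_table(path: str | Path, snp_names: list[str]) -> list[CarrierRecord]:
    """Read a carrier TSV, logging (and dropping) invalid rows."""
    records, _ = load_carrier_table(path, snp_names)
    return records


def write_carrier_table(records: list[CarrierRecord], path: str | Path,
                        snp_names: list[str] | None = None) -> None:
    """Write records as a versioned TSV (round-trip stable)."""
    path = Path(path)
    if snp_names is None:
        seen: dict[str, None] = {}
        for rec in records:
            for s in rec.genotypes:
                seen.setdefault(s)
        snp_names = list(seen)

    def cell(value):
        return "" if value is None else value

    rows = []
    for rec in records:
        row = {
            "individual_id": rec.individual_id,
            "family_id": rec.family_id,
            "study_id": rec.study_id,
            "country": rec.country,
            "gene": rec.gene,
            "birth_year": rec.birth_year,
            "mutation_class": rec.mutation_class,
            "mutation": rec.mutation,
            "age_last_obs": rec.age_last_obs,
            "bc_age": cell(rec.bc_age),
            "oc_age": cell(rec.oc_age),
            "mastectomy_age": cell(rec.mastectomy_age),
            "oophorectomy_age": cell(rec.oophorectomy_age),
            "recruitment_age": cell(rec.recruitment_age),
            "er_status": cell(rec.er_status),
            "double_carrier": int(rec.double_carrier),
        }
        for s in snp_names:
            row[s] = cell(rec.genotypes.get(s))
        rows.append(row)
    cols = (MANDATORY_COLUMNS[:6] + ["mutation_class", "mutation", "age_last_obs",
            "bc_age", "oc_age", "mastectomy_age", "oophorectomy_age",
            "recruitment_age", "er_status", "double_carrier"] + snp_names)
    # mandatory order: individual..birth_year then the rest
    cols = ["individual_id", "family_id", "study_id", "country", "gene",
            "birth_year", "mutation_class", "mutation", "age_last_obs",
            "bc_age", "oc_age", "mastectomy_age", "oophorectomy_age",
            "recruitment_age", "er_status", "double_carrier"] + snp_names
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# {CARRIER_TABLE_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def apply_eligibility(
    records: list[CarrierRecord],
) -> tuple[list[CarrierRecord], list[tuple[CarrierRecord, str]]]:
    """Apply cohort eligibility: drop double carriers and duplicate IDs.

    Carriers of pathogenic mutations in both genes are excluded; duplicate
    ``individual_id`` rows are included only once (first occurrence kept).
    Returns (kept, excluded-with-reason-codes).
    """
    kept: list[CarrierRecord] = []
    excluded: list[tuple[CarrierRecord, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.double_carrier:
            excluded.append((rec, "double_carrier"))
        elif rec.individual_id in seen:
            excluded.append((rec, "duplicate_individual_id"))
        else:
            seen.add(rec.individual_id)
            kept.append(rec)
    for rec, reason in excluded:
        logger.info("excluded %s: %s", rec.individual_id, reason)
    return kept, excluded


# ---------------------------------------------------------------------------
# incidence-curve I/O

def read_incidence(path: str | Path) -> dict[tuple[str, str, str], IncidenceCurve]:
    """Read incidence curves from CSV (disease,gene,cohort_band,age,hazard).

    Returns a dict keyed by (disease, gene, cohort_band).  Ages within one
    curve must be contiguous; negative hazards are a format error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"disease", "gene", "age", "hazard"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"incidence table {path}: missing column(s) "
                         f"{', '.join(sorted(missing))}")
    if "cohort_band" not in df.columns:
        df["cohort_band"] = ""
    df["cohort_band"] = df["cohort_band"].fillna("").astype(str)
    if (df["hazard"] < 0).any():
        bad = df[df["hazard"] < 0].iloc[0]
        raise ValueError(
            f"incidence table {path}: negative hazard at "
            f"({bad['disease']}, {bad['gene']}, age {int(bad['age'])})"
        )
    curves: dict[tuple[str, str, str], IncidenceCurve] = {}
    for (disease, gene, band), grp in df.groupby(
        ["disease", "gene", "cohort_band"], sort=True
    ):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(dtype=int)
        if len(ages) > 1 and not (ages[1:] - ages[:-1] == 1).all():
            raise ValueError(
                f"incidence table {path}: non-contiguous ages for "
                f"({disease}, {gene}, {band or '-'})"
            )
        curves[(disease, gene, band)] = IncidenceCurve(
            disease=disease, gene=gene, cohort_band=band,
            hazard=grp["hazard"].to_numpy(dtype=float), age_min=int(ages[0]),
        )
    return curves


def write_incidence(
    curves: dict[tuple[str, str, str], IncidenceCurve] | list[IncidenceCurve],
    path: str | Path,
) -> None:
    """Write incidence curves to CSV (round-trip inverse of read_incidence)."""
    if isinstance(curves, dict):
        curves = list(curves.values())
    rows = []
    for c in curves:
        for k, h in enumerate(c.hazard):
            rows.append({"disease": c.disease, "gene": c.gene,
                         "cohort_band": c.cohort_band, "age": c.age_min + k,
                         "hazard": h})
    pd.DataFrame(rows).to_csv(path, index=False)
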