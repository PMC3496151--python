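"""Shared fixtures: small synthetic cohorts and toy curves."""

from __future__ import annotations

import numpy as np
import pytest

from carriermod import CarrierRecord, IncidenceCurve, SimConfig, simulate_cohort
from carriermod.hazard_core import AGE_MAX, AGE_MIN

N_AGES = AGE_MAX - AGE_MIN


def make_record(i: int = 0, **kw) -> CarrierRecord:
    base = dict(
        individual_id=f"I{i:04d}", family_id=f"F{i:04d}", study_id="ST00",
        country="C00", gene="BRCA1", birth_year=1950, age_last_obs=55,
    )
    base.update(kw)
    return CarrierRecord(**base)


@pytest.fixture(scope="session")
def flat_curve() -> IncidenceCurve:
    """Constant 1%-per-year breast incidence over the whole grid."""
    return IncidenceCurve("breast", "BRCA1", np.full(N_AGES, 0.01))


@pytest.fixture(scope="session")
def toy_curve() -> IncidenceCurve:
    """Three-interval toy curve: positive hazard only at ages 18-20."""
    h = np.zeros(N_AGES)
    h[:3] = [0.15, 0.20, 0.18]
    return IncidenceCurve("breast", "BRCA1", h)


@pytest.fixture(scope="session")
def small_cohort() -> list[CarrierRecord]:
    """Moderate simulated cohort (one stratum) for smoke-level fits."""
    cfg = SimConfig(seed=421, n_families=500, n_strata=1)
    return simulate_cohort(cfg)


def toy_cohort(n: int = 12, seed: int = 3, n_ages: int = 3,
               q: float = 0.4, beta: float = 0.5,
               haz: tuple[float, ...] = (0.15, 0.20, 0.18)) -> list[CarrierRecord]:
    """Tiny hand-scale cohort on a short effective age grid.

    Events and censoring all happen within the first ``n_ages`` year
    intervals, so brute-force enumeration oracles only need those ages.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        dose = int(rng.binomial(2, q))
        # walk the short grid with genotype-specific hazard
        bc = None
        end = AGE_MIN + n_ages
        for k in range(n_ages):
            lam = haz[k] * np.exp(beta * dose)
            if rng.random() < 1 - np.exp(-lam):
                bc = AGE_MIN + k
                end = bc
                break
        recs.append(make_record(
            i, family_id=f"F{i:04d}", age_last_obs=end if bc is None else end + 1,
            bc_age=bc, genotypes={"SNP1": dose}))
    return recs
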