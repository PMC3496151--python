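"""Brute-force oracles: explicit yearly products and grid searches.

Deliberately written as plain Python loops, independent of the package's
vectorized likelihood machinery, so that agreement is a genuine
cross-check.  Only the first few age intervals of a toy cohort need to be
evaluated, so speed is irrelevant.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

from carriermod.data_io import derive_followup
from carriermod.hazard_core import AGE_MIN


def oracle_loglik_single(records, snp, beta, q, hazard, age_min=AGE_MIN):
    """Retrospective log-likelihood by per-genotype enumeration.

    ``hazard``: list of yearly population hazards starting at ``age_min``.
    Each individual's phenotype likelihood is an explicit product of yearly
    survival factors (and an event density), and the genotype prior is the
    HWE triple; baseline reconstruction is the same forward constraint, but
    computed with scalar arithmetic.
    """
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    # scalar forward reconstruction of the constrained baseline
    surv = [1.0, 1.0, 1.0]
    lam0 = []
    for lam_star in hazard:
        r = [math.exp(beta * g) for g in (0, 1, 2)]
        num = sum(p * s for p, s in zip(probs, surv))
        den = sum(p * s * rg for p, s, rg in zip(probs, surv, r))
        lam = 0.0 if lam_star == 0 else lam_star * num / den
        lam0.append(lam)
        surv = [s * math.exp(-lam * rg) for s, rg in zip(surv, r)]

    total = 0.0
    for rec in records:
        fu = derive_followup(rec, "breast_only")
        lik = []
        for g in (0, 1, 2):
            r = math.exp(beta * g)
            val = 1.0
            for k in range(fu.end_age - age_min):
                val *= math.exp(-lam0[k] * r)
            if fu.status == "breast":
                val *= lam0[fu.end_age - age_min] * r
            lik.append(val)
        gi = rec.genotypes[snp]
        num = lik[gi] * probs[gi]
        den = sum(l * p for l, p in zip(lik, probs))
        total += math.log(num / den)
    return total


def oracle_loglik_competing(records, snp, beta_b, beta_o, q, haz_b, haz_o,
                            age_min=AGE_MIN):
    """Competing-risks enumeration oracle (two cause-specific hazards)."""
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    surv = [1.0, 1.0, 1.0]
    lam0_b, lam0_o = [], []
    for ls_b, ls_o in zip(haz_b, haz_o):
        r_b = [math.exp(beta_b * g) for g in (0, 1, 2)]
        r_o = [math.exp(beta_o * g) for g in (0, 1, 2)]
        num = sum(p * s for p, s in zip(probs, surv))
        den_b = sum(p * s * r for p, s, r in zip(probs, surv, r_b))
        den_o = sum(p * s * r for p, s, r in zip(probs, surv, r_o))
        lb = 0.0 if ls_b == 0 else ls_b * num / den_b
        lo = 0.0 if ls_o == 0 else ls_o * num / den_o
        lam0_b.append(lb)
        lam0_o.append(lo)
        surv = [s * math.exp(-(lb * rb + lo * ro))
                for s, rb, ro in zip(surv, r_b, r_o)]

    total = 0.0
    for rec in records:
        fu = derive_followup(rec, "competing")
        lik = []
        for g in (0, 1, 2):
            rb, ro = math.exp(beta_b * g), math.exp(beta_o * g)
            val = 1.0
            for k in range(fu.bc_end - age_min):
                val *= math.exp(-lam0_b[k] * rb)
            for k in range(fu.oc_end - age_min):
                val *= math.exp(-lam0_o[k] * ro)
            if fu.status == "breast":
                val *= lam0_b[fu.bc_end - age_min] * rb
            elif fu.status == "ovarian":
                val *= lam0_o[fu.oc_end - age_min] * ro
            lik.append(val)
        gi = rec.genotypes[snp]
        total += math.log(lik[gi] * probs[gi]
                          / sum(l * p for l, p in zip(lik, probs)))
    return total


def _profile_q(fn):
    """Maximize fn(q) over q in (0,1); returns the maximum value."""
    res = optimize.minimize_scalar(lambda q: -fn(q), bounds=(1e-4, 1 - 1e-4),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    return -res.fun


def grid_mle_single(records, snp, hazard, lo=-2.0, hi=2.0, step=1e-3):
    """Grid-search MLE of beta (q profiled) on a beta grid of given step."""
    grid = np.arange(lo, hi + step / 2, step)
    best_beta, best_val = None, -np.inf
    for beta in grid:
        val = _profile_q(lambda q, b=beta: oracle_loglik_single(
            records, snp, b, q, hazard))
        if val > best_val:
            best_beta, best_val = beta, val
    return float(best_beta), float(best_val)


def grid_mle_competing(records, snp, haz_b, haz_o, lo=-2.0, hi=2.0,
                       final_step=1e-3):
    """Iteratively refined 2-d grid search over (beta_b, beta_o).

    Three coarse-to-fine passes ending on a local grid of the requested
    final step; q is profiled at every node.
    """
    center = (0.0, 0.0)
    half = (hi - lo) / 2.0
    step = half / 10.0
    while True:
        bs = np.arange(center[0] - half, center[0] + half + step / 2, step)
        os_ = np.arange(center[1] - half, center[1] + half + step / 2, step)
        best, best_val = center, -np.inf
        for bb in bs:
            for bo in os_:
                val = _profile_q(lambda q: oracle_loglik_competing(
                    records, snp, bb, bo, q, haz_b, haz_o))
                if val > best_val:
                    best, best_val = (float(bb), float(bo)), val
        if step <= final_step:
            return best, best_val
        center = best
        half = 2.5 * step
        step = max(final_step, step / 10.0)
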