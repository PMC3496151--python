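"""Cluster-robust (sandwich) covariance for family-clustered carriers.

Relatives in carrier cohorts share a family identifier; their retrospective
log-likelihood contributions are correlated (shared genotype draws, shared
environment), so model-based standard errors understate the uncertainty.
The sandwich estimator A^-1 B A^-1 clusters score contributions by family:
A is the observed information (minus the Hessian of the total
log-likelihood at the MLE) and B sums the outer products of per-family
score sums.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cluster_scores", "sandwich_cov", "numeric_scores", "numeric_hessian"]


def cluster_scores(scores: np.ndarray, clusters) -> np.ndarray:
    """Sum per-individual score vectors within clusters.

    ``scores`` is (n, p); ``clusters`` length-n labels.  Returns (G, p).
    """
    scores = np.asarray(scores, dtype=float)
    labels, inverse = np.unique(np.asarray(clusters), return_inverse=True)
    out = np.zeros((len(labels), scores.shape[1]))
    np.add.at(out, inverse, scores)
    return out


def sandwich_cov(
    scores: np.ndarray,
    hessian: np.ndarray,
    clusters=None,
    small_sample: bool = False,
) -> np.ndarray:
    """Cluster-robust covariance A^-1 B A^-1.

    ``scores``: (n, p) per-individual scores of the log-likelihood at the
    MLE; ``hessian``: (p, p) Hessian of the total log-likelihood (negative
    definite at an interior MLE); ``clusters``: length-n family labels
    (``None`` = every observation its own cluster, the ordinary
    heteroskedasticity-robust sandwich).  ``small_sample`` applies the
    G/(G-1) finite-cluster factor (off by default).
    """
    scores = np.asarray(scores, dtype=float)
    hessian = np.asarray(hessian, dtype=float)
    a = -hessian
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"information matrix is singular or near-singular "
            f"(condition number {cond:.3g})"
        )
    if clusters is None:
        u = scores
    else:
        u = cluster_scores(scores, clusters)
    b = u.T @ u
    if small_sample:
        g = u.shape[0]
        if g > 1:
            b = b * (g / (g - 1))
    a_inv = np.linalg.inv(a)
    cov = a_inv @ b @ a_inv
    return 0.5 * (cov + cov.T)  # symmetrize against round-off


def numeric_scores(per_individual_loglik, theta: np.ndarray,
                   step: float = 1e-5) -> np.ndarray:
    """Central-difference per-individual score matrix U (n, p).

    ``per_individual_loglik(theta)`` must return the length-n vector of
    individual log-likelihood contributions.
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    cols = []
    for j in range(p):
        h = step * max(1.0, abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        cols.append((per_individual_loglik(up) - per_individual_loglik(dn))
                    / (2.0 * h))
    return np.column_stack(cols)


def numeric_hessian(total_loglik, theta: np.ndarray,
                    step: float = 1e-4) -> np.ndarray:
    """Central second-difference Hessian of a scalar function (p, p)."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    hs = step * np.maximum(1.0, np.abs(theta))
    f0 = total_loglik(theta)
    hess = np.zeros((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = hs[i]
        fpp = total_loglik(theta + ei)
        fmm = total_loglik(theta - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / hs[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = hs[j]
            f1 = total_loglik(theta + ei + ej)
            f2 = total_loglik(theta + ei - ej)
            f3 = total_loglik(theta - ei + ej)
            f4 = total_loglik(theta - ei - ej)
            hess[i, j] = hess[j, i] = (f1 - f2 - f3 + f4) / (4.0 * hs[i] * hs[j])
    return hess
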