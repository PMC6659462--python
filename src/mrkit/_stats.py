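"""Shared numerical primitives.

Small, dependency-light helpers used across the estimator modules: the 95%
normal-interval convention, Wald tails, and vectorized per-variant association
scans (the workhorse behind turning an individual-level cohort into a GWAS-style
summary-statistic table without fitting thousands of model objects one by one).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

# CI convention: +/-1.96*SE everywhere, matching how printed 95% intervals
# convert back to Wald p-values.
Z95 = 1.96


def wald_p(beta: np.ndarray | float, se: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal tail probability of beta/se."""
    z = np.abs(np.asarray(beta, dtype=float)) / np.asarray(se, dtype=float)
    p = 2.0 * stats.norm.sf(z)
    return float(p) if np.ndim(p) == 0 else p


def normal_ci(beta: float, se: float) -> tuple[float, float]:
    return beta - Z95 * se, beta + Z95 * se


class ScanResult(NamedTuple):
    """Per-variant simple-regression scan output (one entry per column)."""

    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    flags: np.ndarray  # "" | "monomorphic" | "not_converged"


def linear_scan(y: np.ndarray, G: np.ndarray) -> ScanResult:
    """Simple linear regression of ``y`` on each column of ``G`` separately.

    Closed form: beta_j = cov(g_j, y)/var(g_j); the residual variance uses
    n-2 degrees of freedom, so results agree with an OLS fit per column.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("scan needs at least 3 samples")
    gbar = G.mean(axis=0)
    Gc = G - gbar
    ybar = y.mean()
    yc = y - ybar
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    mono = sxx <= 0
    sxx_safe = np.where(mono, np.nan, sxx)
    beta = (Gc.T @ yc) / sxx_safe
    resid_ss = yc @ yc - beta**2 * sxx_safe
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(np.maximum(sigma2, 0.0) / sxx_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    flags = np.where(mono, "monomorphic", "")
    return ScanResult(beta, se, pval, flags.astype(object))


def logistic_scan(y: np.ndarray, G: np.ndarray, max_iter: int = 40,
                  tol: float = 1e-8) -> ScanResult:
    """Per-column logistic regression y ~ 1 + g_j, fitted jointly by Newton.

    Each variant has its own (intercept, slope); the Newton step solves the
    2x2 system per column, vectorized across columns. Monomorphic columns are
    flagged and returned with NaN slope/SE instead of being dropped silently.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n, k = G.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic scan requires a 0/1 outcome")
    mono = G.std(axis=0) <= 0
    if y.min() == y.max():
        nanarr = np.full(k, np.nan)
        return ScanResult(nanarr, nanarr.copy(), nanarr.copy(),
                          np.full(k, "monomorphic", dtype=object))

    ybar = y.mean()
    b0 = np.full(k, np.log(ybar / (1.0 - ybar)))
    b1 = np.zeros(k)
    active = ~mono
    for _ in range(max_iter):
        eta = b0[None, :] + G * b1[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", G, r)
        w = p * (1.0 - p)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", G, w)
        h11 = np.einsum("ij,ij,ij->j", G, G, w)
        det = h00 * h11 - h01 * h01
        det = np.where(det <= 0, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # damp exploding steps (quasi-separated variants)
        step = np.sqrt(d0**2 + d1**2)
        damp = np.where(step > 5.0, 5.0 / step, 1.0)
        b0 = np.where(active, b0 + damp * d0, b0)
        b1 = np.where(active, b1 + damp * d1, b1)
        conv = np.maximum(np.abs(g0), np.abs(g1)) < tol * n
        active = active & ~conv
        if not active.any():
            break

    eta = b0[None, :] + G * b1[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    h00 = w.sum(axis=0)
    h01 = np.einsum("ij,ij->j", G, w)
    h11 = np.einsum("ij,ij,ij->j", G, G, w)
    det = h00 * h11 - h01 * h01
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / det, np.nan))
    beta = np.where(mono, np.nan, b1)
    se1 = np.where(mono, np.nan, se1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(beta) / se1)
    flags = np.full(k, "", dtype=object)
    flags[mono] = "monomorphic"
    flags[active & ~mono] = "not_converged"
    return ScanResult(beta, se1, pval, flags)
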