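"""Two-sample (summary-statistic) Mendelian-randomization estimators.

All estimators consume a harmonized pair table (columns ``bx, se_x, by,
se_y`` plus ``snp``) in which exposure and outcome effects refer to the same
effect allele:

* Wald ratio — single-variant by/bx with the first-order delta SE;
* IVW — inverse-variance-weighted regression of by on bx through the origin,
  fixed-effect or with multiplicative overdispersion (random);
* MR-Egger — weighted regression with a free intercept; the intercept
  estimates average directional pleiotropy, the slope the causal effect under
  InSIDE. Pairs are oriented to bx > 0 first (the estimator is not
  orientation-invariant without it);
* weighted median / penalized weighted median — the interpolated 50% point of
  the ratio distribution under weights bx^2/se_y^2, consistent while <50% of
  the weight comes from invalid instruments; SE by seeded parametric
  bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .onesample import MREstimate

__all__ = [
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
]

_REQUIRED = ("bx", "se_x", "by", "se_y")


@dataclass
class HeterogeneityResult:
    """Cochran's Q among per-variant causal estimates."""

    q: float
    df: int
    p_q: float
    i2: float

    @classmethod
    def from_q(cls, q: float, df: int) -> "HeterogeneityResult":
        p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        return cls(q=float(q), df=int(df), p_q=p, i2=float(i2))


def _columns(pairs: pd.DataFrame) -> tuple[np.ndarray, ...]:
    missing = [c for c in _REQUIRED if c not in pairs.columns]
    if missing:
        raise ValueError(f"pair table missing column(s) {missing}")
    bx = pairs["bx"].to_numpy(dtype=float)
    se_x = pairs["se_x"].to_numpy(dtype=float)
    by = pairs["by"].to_numpy(dtype=float)
    se_y = pairs["se_y"].to_numpy(dtype=float)
    if np.any(se_y <= 0) or np.any(se_x <= 0):
        raise ValueError("standard errors must be positive")
    return bx, se_x, by, se_y


def wald_ratio(pair: pd.Series | dict) -> MREstimate:
    """Single-variant causal estimate by/bx with SE = se_y/|bx|."""
    bx, by, se_y = float(pair["bx"]), float(pair["by"]), float(pair["se_y"])
    if bx == 0:
        raise ValueError("Wald ratio undefined for bx = 0")
    return MREstimate.from_beta_se("wald_ratio", by / bx, se_y / abs(bx), n_variants=1)


def ivw(pairs: pd.DataFrame, model: str = "fixed") -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate (regression through the origin).

    estimate = sum(w bx by) / sum(w bx^2) with w = 1/se_y^2;
    SE_fixed = (sum w bx^2)^(-1/2); the random model inflates the SE by
    max(1, sqrt(Q/(k-1))) (multiplicative overdispersion).
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    bx, _, by, se_y = _columns(pairs)
    k = bx.size
    if k < 2:
        raise ValueError("IVW requires >=2 pairs; use wald_ratio for a single variant")
    w = 1.0 / se_y**2
    sxx = np.sum(w * bx * bx)
    if sxx == 0:
        raise ValueError("all bx are zero; IVW undefined")
    beta = float(np.sum(w * bx * by) / sxx)
    se = float(1.0 / np.sqrt(sxx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    het = HeterogeneityResult.from_q(q, k - 1)
    if model == "random":
        se *= max(1.0, np.sqrt(q / (k - 1)))
    est = MREstimate.from_beta_se(f"ivw_{model}", beta, se, n_variants=k,
                                  q=het.q, df=het.df, p_q=het.p_q, i2=het.i2)
    return est, het


def egger(pairs: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression by = b0 + b1 bx with weights 1/se_y^2.

    Returns (slope estimate, intercept estimate). Pairs are reoriented so
    every bx > 0 before fitting. SEs use multiplicative overdispersion
    floored at 1 (classical weighted least squares when the fit is
    underdispersed), the usual summary-MR convention.
    """
    bx, _, by, se_y = _columns(pairs)
    k = bx.size
    if k < 3:
        raise ValueError("MR-Egger requires >=3 pairs (intercept + slope + 1 df)")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("all bx identical after orientation; Egger design is rank-deficient")
    w = 1.0 / se_y**2
    X = np.column_stack([np.ones(k), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(XtWX) * max(1.0, sigma2)
    se0, se1 = np.sqrt(np.diag(cov))
    slope = MREstimate.from_beta_se("egger_slope", coef[1], se1, n_variants=k)
    intercept = MREstimate.from_beta_se("egger_intercept", coef[0], se0,
                                        scale="linear", n_variants=k)
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / total
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(pairs: pd.DataFrame, penalized: bool = False,
                    bootstrap_reps: int = 1000, seed: int = 0) -> MREstimate:
    """(Penalized) weighted-median causal estimate.

    Per-variant ratios r_j = by_j/bx_j are weighted by w_j = bx_j^2/se_y_j^2
    and the estimate is the linear interpolation of the weighted empirical CDF
    at probability 0.5. The penalized variant downweights outliers by
    multiplying w_j with min(1, 20 q_j), where q_j is the upper chi^2_1 tail
    of variant j's contribution to Cochran's Q about the unpenalized median.
    The SE is a seeded parametric bootstrap resampling (bx_j, by_j) from
    normal distributions with their reported SEs.
    """
    bx, se_x, by, se_y = _columns(pairs)
    k = bx.size
    if k < 3:
        raise ValueError("weighted median requires >=3 pairs")
    if np.any(bx == 0):
        raise ValueError("weighted median undefined with bx = 0 entries")

    def point(bx_, by_):
        ratios = by_ / bx_
        w = bx_**2 / se_y**2
        if penalized:
            beta0 = _weighted_median_point(ratios, w)
            q_contrib = w * (ratios - beta0) ** 2
            penalty = np.minimum(1.0, 20.0 * stats.chi2.sf(q_contrib, 1))
            w = w * penalty
        return _weighted_median_point(ratios, w)

    beta = point(bx, by)
    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        bx_b = bx + rng.normal(scale=se_x)
        by_b = by + rng.normal(scale=se_y)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        boot[b] = point(bx_b, by_b)
    se = float(boot.std(ddof=1))
    method = "penalized_weighted_median" if penalized else "weighted_median"
    if se == 0:
        # degenerate bootstrap (all ratios identical); report a tiny SE floor
        se = np.finfo(float).eps
    return MREstimate.from_beta_se(method, beta, se, n_variants=k)
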