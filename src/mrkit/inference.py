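"""Auxiliary inferential procedures around the MR estimators.

Everything here operates on (estimate, SE) summaries or harmonized pair
tables: recovering Wald p-values from printed estimate/CI pairs, the Fisher
z-score comparison of two independent estimates (the sex-difference test),
fixed-effect inverse-variance meta-analysis with Cochran's Q, the
over-identification contrast between disjoint instrument subsets, the
per-variant pleiotropy screen with its odds-ratio-to-SD conversion, and the
negative-control battery run on a simulated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import Z95, wald_p
from .onesample import MREstimate, iv_two_stage
from .twosample import HeterogeneityResult, ivw

__all__ = [
    "EstimateWithSE",
    "SubsetComparison",
    "estimate_from_ci",
    "wald_p_from_ci",
    "fisher_z_diff",
    "meta_fixed",
    "compare_estimates",
    "overidentification_test",
    "pleiotropy_screen",
    "negative_control_battery",
]


@dataclass
class EstimateWithSE:
    """A labelled effect estimate with its standard error (log-odds or linear)."""

    beta: float
    se: float
    ci_low: float | None = None
    ci_high: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.beta <= self.ci_high):
                raise ValueError("beta must lie inside its CI")


def estimate_from_ci(value: float, ci_low: float, ci_high: float,
                     scale: str = "linear", label: str = "") -> EstimateWithSE:
    """Back out (beta, SE) from a printed estimate and 95% CI.

    ``scale='log_odds_from_or'`` takes an odds ratio with its CI and works on
    the log scale; ``'linear'`` takes the values as-is. SE = (hi - lo)/(2*1.96),
    the convention that reproduces printed p-values from printed intervals.
    """
    if ci_low >= ci_high:
        raise ValueError("ci_low must be smaller than ci_high")
    if scale == "log_odds_from_or":
        if min(value, ci_low, ci_high) <= 0:
            raise ValueError("odds-ratio inputs must be positive")
        value, ci_low, ci_high = np.log(value), np.log(ci_low), np.log(ci_high)
    elif scale != "linear":
        raise ValueError("scale must be 'log_odds_from_or' or 'linear'")
    se = (ci_high - ci_low) / (2.0 * Z95)
    return EstimateWithSE(beta=float(value), se=float(se),
                          ci_low=float(ci_low), ci_high=float(ci_high), label=label)


def wald_p_from_ci(value: float, ci_low: float, ci_high: float,
                   scale: str = "linear") -> float:
    """Two-sided Wald p-value implied by a printed estimate and its 95% CI."""
    est = estimate_from_ci(value, ci_low, ci_high, scale=scale)
    return float(wald_p(est.beta, est.se))


def fisher_z_diff(a: EstimateWithSE, b: EstimateWithSE) -> tuple[float, float]:
    """Fisher z comparison of two independent estimates.

    z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    Antisymmetric in its arguments for z, symmetric for p.
    """
    z = (a.beta - b.beta) / np.hypot(a.se, b.se)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def meta_fixed(estimates: Sequence[EstimateWithSE | MREstimate],
               ) -> tuple[MREstimate, HeterogeneityResult]:
    """Fixed-effect inverse-variance meta-analysis.

    pooled = sum(w beta)/sum(w) with w = 1/se^2; SE = (sum w)^(-1/2);
    Cochran's Q about the pooled mean with k-1 df. A single estimate is
    returned unchanged (Q = 0).
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("meta_fixed needs at least one estimate")
    beta = np.array([e.beta if isinstance(e, EstimateWithSE) else e.estimate for e in ests],
                    dtype=float)
    se = np.array([e.se for e in ests], dtype=float)
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (beta - pooled) ** 2))
    het = HeterogeneityResult.from_q(q, len(ests) - 1)
    est = MREstimate.from_beta_se("meta_fixed", pooled, pooled_se,
                                  n_variants=len(ests), q=het.q, df=het.df,
                                  p_q=het.p_q, i2=het.i2)
    return est, het


def _as_estimate(e: EstimateWithSE | MREstimate, label: str) -> EstimateWithSE:
    if isinstance(e, EstimateWithSE):
        return e
    return EstimateWithSE(beta=e.estimate, se=e.se, ci_low=e.ci_low,
                          ci_high=e.ci_high, label=label or e.method)


@dataclass
class SubsetComparison:
    """Over-identification contrast between two instrument subsets."""

    estimate_a: EstimateWithSE
    estimate_b: EstimateWithSE
    z: float
    p_difference: float


def compare_estimates(a: EstimateWithSE | MREstimate, b: EstimateWithSE | MREstimate,
                      label_a: str = "A", label_b: str = "B") -> SubsetComparison:
    """Fisher-z contrast of two already-computed causal estimates."""
    ea, eb = _as_estimate(a, label_a), _as_estimate(b, label_b)
    z, p = fisher_z_diff(ea, eb)
    return SubsetComparison(estimate_a=ea, estimate_b=eb, z=z, p_difference=p)


def overidentification_test(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame,
                            label_a: str = "A", label_b: str = "B") -> SubsetComparison:
    """Consistency of causal estimates from two disjoint instrument subsets.

    Fits fixed-effect IVW within each subset and contrasts the estimates by
    Fisher z. Disagreement (small p_difference) indicates at least one subset
    violates the IV assumptions. Subsets sharing variants are refused.
    """
    snps_a, snps_b = set(pairs_a["snp"]), set(pairs_b["snp"])
    overlap = snps_a & snps_b
    if overlap:
        raise ValueError(f"instrument subsets overlap: {sorted(overlap)[:5]}...")
    est_a, _ = ivw(pairs_a, model="fixed")
    est_b, _ = ivw(pairs_b, model="fixed")
    return compare_estimates(est_a, est_b, label_a, label_b)


def pleiotropy_screen(pairs: pd.DataFrame, case_fraction: float,
                      sd_conversion: float | None = None) -> pd.DataFrame:
    """Flag variants with larger outcome than exposure effects.

    The outcome log-odds per allele is converted to SD units of the liability
    via by_SD = by * sqrt(c (1 - c)) with c the outcome case fraction
    (``sd_conversion`` overrides the constant); the exposure effect bx is
    already in SD units. A variant is flagged when |by_SD| > |bx| — such a
    variant is unlikely to act on the outcome through the exposure.
    """
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must lie in (0, 1)")
    conv = sd_conversion if sd_conversion is not None else float(
        np.sqrt(case_fraction * (1.0 - case_fraction)))
    by_sd = pairs["by"].to_numpy(dtype=float) * conv
    bx = pairs["bx"].to_numpy(dtype=float)
    return pd.DataFrame({
        "snp": pairs["snp"],
        "bx": bx,
        "by": pairs["by"],
        "by_sd": by_sd,
        "flagged": np.abs(by_sd) > np.abs(bx),
    })


def negative_control_battery(controls: pd.DataFrame, exposure: np.ndarray,
                             score: np.ndarray, sep_covariate: np.ndarray,
                             ) -> pd.DataFrame:
    """Observational and IV estimates for traits the exposure cannot cause.

    For each control trait, four models are fitted: observational regression
    of the trait on the exposure and the two-stage IV estimate, each with and
    without the socioeconomic-position-like covariate. Continuous controls
    use a linear second stage, binary controls a logistic one. With a valid
    instrument the IV intervals should cover zero; association that vanishes
    on SEP adjustment points at residual stratification/confounding rather
    than causation.
    """
    import statsmodels.api as sm

    x = np.asarray(exposure, dtype=float)
    s = np.asarray(score, dtype=float)
    sep = np.asarray(sep_covariate, dtype=float)
    rows = []
    for name in controls.columns:
        c = controls[name].to_numpy(dtype=float)
        binary = set(np.unique(c)) <= {0.0, 1.0}
        family = "logistic" if binary else "linear"
        for adjusted in (False, True):
            cov = sep if adjusted else None
            # observational: control ~ exposure (+ sep)
            design = sm.add_constant(x if cov is None else np.column_stack([x, cov]))
            if binary:
                fit = sm.Logit(c, design).fit(disp=0)
            else:
                fit = sm.OLS(c, design).fit()
            obs = MREstimate.from_beta_se("observational", fit.params[1], fit.bse[1],
                                          scale="log_odds" if binary else "linear",
                                          n_samples=int(c.size))
            iv = iv_two_stage(c, x, s, covariates=cov, second_stage=family)
            for est in (obs, iv):
                rows.append({
                    "control": name, "family": family,
                    "estimator": "iv" if est.method == "tsls" else "observational",
                    "adjusted": adjusted,
                    "estimate": est.estimate, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
                })
    return pd.DataFrame(rows)
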