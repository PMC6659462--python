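"""Synthetic biobank-style cohort generator for Mendelian-randomization studies.

Generates individual-level cohorts with the statistical structure a one-sample
MR analysis of a continuous, confounded exposure (think BMI in SD units) on a
binary outcome (think depression case/control) assumes:

* biallelic instrument variants in Hardy-Weinberg proportions,
* per-variant exposure effects calibrated so the weighted score explains an
  exact target fraction of exposure variance (1.7% for a BMI-like instrument,
  0.2% for a weak favourable-adiposity-like instrument),
* a logistic outcome with a tunable causal log-odds per SD exposure, an
  intercept solved numerically to hit a target case fraction,
* optional directional or balanced horizontal pleiotropy,
* a sex-specific multiplier on the causal effect,
* negative-control traits driven by the confounder (and, optionally, by a
  genotype-correlated stratification axis) but never by the exposure itself.

Because the second stage is logistic, the IV estimand is the *marginal*
log-odds ratio, which is not the conditional ``theta`` written into the model
(non-collapsibility). :func:`oracle_estimand` therefore computes the estimand
empirically on a very large cohort once per configuration; recovery tests
should target that value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._stats import ScanResult, linear_scan, logistic_scan

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "TrueParameters",
    "CohortTable",
    "simulate_genotypes",
    "calibrate_effects",
    "simulate_cohort",
    "cohort_to_summary_stats",
    "simulate_summary_pairs",
    "oracle_estimand",
    "write_cohort",
    "read_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# named sub-streams derived from the root seed; order is part of the
# reproducibility contract and must not change between releases
_STREAMS = (
    "freqs", "alpha", "delta", "alleles", "subsets", "genotypes",
    "confounder", "noise", "sex", "outcome", "covariates", "controls",
    "summary", "oracle",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic MR cohort.

    Defaults mirror the analysis conditions of a large one-sample biobank MR
    of BMI and depression: 73 instrument variants explaining 1.7% of exposure
    variance, case fraction 41 397/287 503 ~= 0.144, and a causal log-odds of
    0.166 per SD exposure (odds ratio 1.18).
    """

    n_samples: int = 287_503
    n_variants: int = 73
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_r2: float = 0.017
    causal_effect: float = 0.166
    confounder_effect_x: float = 0.3
    confounder_effect_y: float = 0.4
    pleiotropy_fraction: float = 0.0
    pleiotropy_mode: str = "balanced"
    pleiotropy_scale: float = 0.02
    case_fraction: float = 41_397 / 287_503
    sex_effect_modifier: float = 1.0
    stratification_effect: float = 0.0
    palindromic_fraction: float = 0.0
    seed: int = 2019

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ConfigError("n_samples and n_variants must be positive")
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.target_r2 < 1):
            raise ConfigError("target_r2 must lie in [0, 1)")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ConfigError("pleiotropy_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ConfigError("pleiotropy_mode must be 'balanced' or 'directional'")
        if not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must lie in (0, 1)")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ConfigError("palindromic_fraction must lie in [0, 1]")
        for name in ("causal_effect", "confounder_effect_x", "confounder_effect_y",
                     "pleiotropy_scale", "sex_effect_modifier", "stratification_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.target_r2 + self.confounder_effect_x**2 >= 1:
            raise ConfigError(
                "target_r2 + confounder_effect_x^2 must be < 1 so the residual "
                "exposure variance is positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-purpose generator derived from the root seed."""
        idx = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), idx]))

    def variant_ids(self) -> list[str]:
        return [f"rs{1000 + j}" for j in range(self.n_variants)]


@dataclass
class TrueParameters:
    """Ground truth of one generative configuration.

    ``theta`` is the conditional causal log-odds written into the outcome
    model; ``oracle_estimand`` (filled by :func:`oracle_estimand`) is the
    marginal quantity a two-stage IV analysis actually estimates.
    """

    freqs: np.ndarray
    alpha: np.ndarray                 # per-variant exposure effects
    delta: np.ndarray                 # per-variant direct outcome effects
    confounder_effect_x: float
    confounder_effect_y: float
    theta: float
    effect_alleles: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    other_alleles: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    beta0: float | None = None        # outcome intercept (solved at simulation time)
    oracle_estimand: float | None = None

    @property
    def genetic_variance(self) -> float:
        return float(np.sum(2.0 * self.freqs * (1.0 - self.freqs) * self.alpha**2))


@dataclass
class CohortTable:
    """Individual-level cohort: dosages, exposure, outcome, sex, covariates.

    ``covariates`` holds a confounder proxy, a centre-like categorical factor,
    a socioeconomic-position-like variable (``sep``) and a trait downstream of
    the exposure (``downstream``); ``controls`` holds one continuous and one
    binary negative-control trait that never depend on the exposure.
    """

    sample_id: np.ndarray
    variant_ids: list[str]
    dosages: np.ndarray               # (n_samples, n_variants) int8 in {0,1,2}
    exposure: np.ndarray              # unit-SD scale
    outcome: np.ndarray               # 0/1
    sex: np.ndarray                   # 0 = male, 1 = female
    covariates: pd.DataFrame
    controls: pd.DataFrame
    variants: pd.DataFrame            # snp, effect_allele, other_allele, freq

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame({
            "sample_id": self.sample_id,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "sex": self.sex,
        })
        return pd.concat(
            [base, self.covariates.reset_index(drop=True),
             self.controls.reset_index(drop=True), self.dosage_frame()],
            axis=1)


def simulate_genotypes(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw Hardy-Weinberg dosages: column j ~ Binomial(2, f_j) i.i.d.

    Returns the (n_samples, n_variants) int8 dosage matrix and the allele
    frequency vector actually used (shared with :func:`calibrate_effects`
    through the seeded ``freqs`` stream).
    """
    freqs = _draw_freqs(config)
    rng = config.rng("genotypes")
    g = rng.binomial(2, freqs[None, :], size=(config.n_samples, config.n_variants))
    return g.astype(np.int8), freqs


def _draw_freqs(config: SimulationConfig) -> np.ndarray:
    lo, hi = config.maf_range
    return config.rng("freqs").uniform(lo, hi, size=config.n_variants)


def calibrate_effects(config: SimulationConfig) -> TrueParameters:
    """Draw per-variant effects and rescale to the target score R-squared.

    Exposure effects alpha_j are half-normal draws rescaled so that
    ``sum_j 2 f_j (1 - f_j) alpha_j**2`` equals ``target_r2`` exactly (the
    exposure has unit theoretical variance). Direct outcome effects delta_j
    are zero outside the configured pleiotropy fraction; directional mode
    draws them with a common (positive) sign, balanced mode with mean zero.
    """
    freqs = _draw_freqs(config)
    k = config.n_variants

    if config.target_r2 == 0:
        alpha = np.zeros(k)
    else:
        raw = np.abs(config.rng("alpha").normal(size=k)) + 0.1
        raw_var = np.sum(2.0 * freqs * (1.0 - freqs) * raw**2)
        alpha = raw * np.sqrt(config.target_r2 / raw_var)

    delta = np.zeros(k)
    n_pleio = int(round(config.pleiotropy_fraction * k))
    if n_pleio > 0:
        rng_d = config.rng("delta")
        idx = rng_d.choice(k, size=n_pleio, replace=False)
        if config.pleiotropy_mode == "directional":
            vals = config.pleiotropy_scale * np.abs(rng_d.normal(size=n_pleio))
        else:
            vals = config.pleiotropy_scale * rng_d.normal(size=n_pleio)
        delta[idx] = vals

    # effect allele "A" throughout; palindromic (strand-ambiguous) variants
    # get "T" as the other allele, the rest "G"
    palindromic = config.rng("alleles").random(k) < config.palindromic_fraction
    effect = np.full(k, "A", dtype=object)
    other = np.where(palindromic, "T", "G").astype(object)

    return TrueParameters(
        freqs=freqs, alpha=alpha, delta=delta,
        confounder_effect_x=config.confounder_effect_x,
        confounder_effect_y=config.confounder_effect_y,
        theta=config.causal_effect,
        effect_alleles=effect, other_alleles=other,
    )


def _solve_intercept(eta: np.ndarray, case_fraction: float) -> float:
    """Bisection for the outcome intercept hitting the target prevalence.

    Solves mean(expit(b0 + eta)) = case_fraction on the simulated linear
    predictors; the expected prevalence is monotone in b0 so a bracketed
    root always exists.
    """
    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - case_fraction
    return brentq(f, -30.0, 30.0, xtol=1e-6)


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, TrueParameters]:
    """Generate a full cohort plus its ground-truth parameters.

    Exposure: X = sum_j alpha_j (g_j - 2 f_j) + c_x U + sigma eps, with
    sigma chosen so Var(X) = 1 theoretically. Outcome:
    logit P(Y=1) = b0 + theta * m(sex) * X + sum_j delta_j g_j + c_y U,
    with b0 solved so the expected prevalence equals ``case_fraction``.
    """
    tp = calibrate_effects(config)
    g, freqs = simulate_genotypes(config)
    n = config.n_samples

    U = config.rng("confounder").normal(size=n)
    sex = (config.rng("sex").random(n) < 0.5).astype(np.int8)

    # genetic component, centered; accumulate per variant to avoid a large
    # float copy of the dosage matrix at biobank n
    gc = np.zeros(n)
    for j in range(config.n_variants):
        if tp.alpha[j] != 0.0:
            gc += tp.alpha[j] * (g[:, j] - 2.0 * freqs[j])

    resid_var = 1.0 - config.target_r2 - config.confounder_effect_x**2
    eps = config.rng("noise").normal(size=n)
    X = gc + config.confounder_effect_x * U + np.sqrt(resid_var) * eps

    modifier = np.where(sex == 1, config.sex_effect_modifier, 1.0)
    eta = tp.theta * modifier * X + config.confounder_effect_y * U
    if np.any(tp.delta != 0.0):
        for j in np.nonzero(tp.delta)[0]:
            eta += tp.delta[j] * g[:, j].astype(float)
    if not np.all(np.isfinite(eta)):
        raise ConfigError("non-finite linear predictor; check parameters")
    beta0 = _solve_intercept(eta, config.case_fraction)
    tp.beta0 = beta0
    Y = (config.rng("outcome").random(n) < expit(beta0 + eta)).astype(np.int8)

    # stratification axis: the standardized genetic-score direction
    if config.target_r2 > 0:
        strat_axis = gc / np.sqrt(config.target_r2)
    else:
        w = 1.0 / np.sqrt(np.sum(2.0 * freqs * (1.0 - freqs)))
        strat_axis = w * (g.astype(float) - 2.0 * freqs[None, :]).sum(axis=1)

    rng_cov = config.rng("covariates")
    s = config.stratification_effect
    sep = 0.8 * U + s * strat_axis + 0.6 * rng_cov.normal(size=n)
    covariates = pd.DataFrame({
        "confounder_proxy": U + 0.5 * rng_cov.normal(size=n),
        "centre": rng_cov.integers(0, 10, size=n).astype(np.int16),
        "sep": sep,
        "downstream": 0.6 * X + 0.8 * rng_cov.normal(size=n),
    })

    # negative controls: driven by the SEP-like trait (hence by U, and by the
    # stratification axis when s != 0) but never by X
    rng_ctl = config.rng("controls")
    control_cont = 0.8 * sep + 0.6 * rng_ctl.normal(size=n)
    control_bin = (rng_ctl.random(n) < expit(-1.8 + 0.8 * sep)).astype(np.int8)
    controls = pd.DataFrame({
        "control_cont": control_cont,
        "control_bin": control_bin,
    })

    variants = pd.DataFrame({
        "snp": config.variant_ids(),
        "effect_allele": tp.effect_alleles,
        "other_allele": tp.other_alleles,
        "freq": freqs,
    })

    cohort = CohortTable(
        sample_id=np.arange(n, dtype=np.int64),
        variant_ids=config.variant_ids(),
        dosages=g, exposure=X, outcome=Y, sex=sex,
        covariates=covariates, controls=controls, variants=variants,
    )
    return cohort, tp


def cohort_to_summary_stats(cohort: CohortTable, trait: str = "exposure") -> pd.DataFrame:
    """Per-variant GWAS-style scan of a cohort trait on each dosage column.

    Continuous traits use simple linear regression (closed form), binary
    traits a per-variant logistic regression; both are vectorized across
    variants. Monomorphic variants are flagged, never silently dropped.

    ``trait`` is ``"exposure"``, ``"outcome"`` or a column of the controls
    table.
    """
    if trait == "exposure":
        y, binary = cohort.exposure, False
    elif trait == "outcome":
        y, binary = cohort.outcome, True
    elif trait in cohort.controls.columns:
        y = cohort.controls[trait].to_numpy()
        binary = set(np.unique(y)) <= {0, 1}
    else:
        raise KeyError(f"unknown trait {trait!r}")

    G = cohort.dosages.astype(np.float64)
    res: ScanResult = logistic_scan(np.asarray(y, float), G) if binary else linear_scan(np.asarray(y, float), G)
    return pd.DataFrame({
        "SNP": cohort.variant_ids,
        "effect_allele": cohort.variants["effect_allele"].to_numpy(),
        "other_allele": cohort.variants["other_allele"].to_numpy(),
        "eaf": G.mean(axis=0) / 2.0,
        "beta": res.beta,
        "se": res.se,
        "pval": res.pval,
        "n": cohort.n_samples,
        "flag": res.flags,
    })


def simulate_summary_pairs(
    n_variants: int = 73,
    theta: float = 0.166,
    mean_bx: float = 0.025,
    se_x: float = 0.003,
    se_y: float = 0.02,
    pleiotropy_fraction: float = 0.0,
    pleiotropy_mode: str = "balanced",
    pleiotropy_scale: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct two-sample summary-statistic generator.

    Draws true per-allele exposure effects, then noisy (bx, by) pairs
    by ~ N(theta * alpha + delta, se_y), bx ~ N(alpha, se_x) — the harmonized
    input of the summary-data estimators, without an individual-level detour.
    Useful for large Monte-Carlo batteries where only the two-sample stage is
    under test.
    """
    rng = np.random.default_rng(seed)
    alpha = mean_bx * (0.4 + np.abs(rng.normal(size=n_variants)))
    delta = np.zeros(n_variants)
    n_pleio = int(round(pleiotropy_fraction * n_variants))
    if n_pleio > 0:
        idx = rng.choice(n_variants, size=n_pleio, replace=False)
        if pleiotropy_mode == "directional":
            delta[idx] = pleiotropy_scale * np.abs(rng.normal(size=n_pleio))
        else:
            delta[idx] = pleiotropy_scale * rng.normal(size=n_pleio)
    bx = alpha + rng.normal(scale=se_x, size=n_variants)
    by = theta * alpha + delta + rng.normal(scale=se_y, size=n_variants)
    return pd.DataFrame({
        "snp": [f"rs{1000 + j}" for j in range(n_variants)],
        "bx": bx, "se_x": se_x, "by": by, "se_y": se_y,
    })


@lru_cache(maxsize=8)
def _oracle_cached(config: SimulationConfig, n_oracle: int) -> float:
    from .onesample import iv_two_stage  # local import: avoid a cycle

    oracle_seed = int(np.random.SeedSequence([int(config.seed), 9999]).generate_state(1)[0] % (2**31))
    big = dataclasses.replace(config, n_samples=n_oracle, seed=oracle_seed)
    cohort, tp = simulate_cohort(big)
    score = np.zeros(n_oracle)
    for j in range(big.n_variants):
        if tp.alpha[j] != 0.0:
            score += tp.alpha[j] * cohort.dosages[:, j]
    est = iv_two_stage(cohort.outcome, cohort.exposure, score)
    return float(est.estimate)


def oracle_estimand(config: SimulationConfig, n_oracle: int = 2_000_000) -> float:
    """Marginal IV estimand theta* of a configuration.

    Runs the one-sample two-stage estimator on a single very large cohort
    drawn from the same generative law (dedicated seed stream). Because the
    second stage is logistic, theta* differs slightly from the conditional
    ``theta`` (non-collapsibility); recovery tests should compare against
    theta*, which is exact up to O(1/sqrt(n_oracle)) Monte-Carlo error.
    """
    if config.target_r2 <= 0:
        raise ConfigError("oracle estimand undefined without a genetic first stage")
    return _oracle_cached(config, n_oracle)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Tab-separated export with header; missing values as 'NA'."""
    cohort.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path: str | Path, n_variants: int | None = None) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`.

    Variant columns are recognized by their 'rs' prefix; allele metadata is
    not stored in the cohort file, so exported variants get default A/G
    labels.
    """
    df = pd.read_csv(path, sep="\t", na_values="NA")
    variant_cols = [c for c in df.columns if c.startswith("rs")]
    if n_variants is not None and len(variant_cols) != n_variants:
        raise ValueError(f"expected {n_variants} variant columns, found {len(variant_cols)}")
    covariate_cols = [c for c in ("confounder_proxy", "centre", "sep", "downstream") if c in df]
    control_cols = [c for c in ("control_cont", "control_bin") if c in df]
    dosages = df[variant_cols].to_numpy(dtype=np.int8)
    variants = pd.DataFrame({
        "snp": variant_cols,
        "effect_allele": "A",
        "other_allele": "G",
        "freq": dosages.mean(axis=0) / 2.0,
    })
    return CohortTable(
        sample_id=df["sample_id"].to_numpy(),
        variant_ids=variant_cols,
        dosages=dosages,
        exposure=df["exposure"].to_numpy(dtype=float),
        outcome=df["outcome"].to_numpy(dtype=np.int8),
        sex=df["sex"].to_numpy(dtype=np.int8),
        covariates=df[covariate_cols].copy(),
        controls=df[control_cols].copy(),
        variants=variants,
    )
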