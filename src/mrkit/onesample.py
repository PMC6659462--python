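"""One-sample instrumental-variable estimation for binary outcomes.

Implements the two-stage procedure used when individual-level genotype,
exposure and outcome data are available: a linear first stage of the exposure
on the genetic risk score, then a logistic (or linear) second stage of the
outcome on the genotype-predicted exposure, with heteroskedasticity-robust
(HC1) standard errors to account for the generated-regressor uncertainty.
The matching observational logistic model and a sex-stratified runner live
here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._stats import Z95, wald_p
from .score import instrument_strength

__all__ = [
    "MREstimate",
    "SeparationError",
    "StratumError",
    "WeakInstrumentWarning",
    "observational_logistic",
    "iv_two_stage",
    "sex_stratified",
]


class SeparationError(ValueError):
    """Logistic fit failed by (quasi-)separation; a penalized fit is needed."""


class StratumError(ValueError):
    """A stratified analysis received an empty stratum."""


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class MREstimate:
    """Method-tagged causal estimate on the log-odds (or declared linear) scale."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    scale: str = "log_odds"
    n_samples: int | None = None
    n_variants: int | None = None
    q: float | None = None
    df: int | None = None
    p_q: float | None = None
    i2: float | None = None
    first_stage_f: float | None = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, **kw) -> "MREstimate":
        if se <= 0:
            raise ValueError("standard error must be positive")
        return cls(method=method, estimate=float(beta), se=float(se),
                   ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
                   p=float(wald_p(beta, se)), **kw)

    @property
    def odds_ratio(self) -> float:
        if self.scale != "log_odds":
            raise ValueError("odds ratio only defined on the log-odds scale")
        return float(np.exp(self.estimate))

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def _design(main: np.ndarray, covariates=None) -> np.ndarray:
    cols = [np.asarray(main, dtype=float)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    return sm.add_constant(np.column_stack(cols))


def observational_logistic(outcome: np.ndarray, exposure: np.ndarray,
                           covariates=None) -> MREstimate:
    """Maximum-likelihood logistic regression of outcome on exposure.

    The estimate is the exposure coefficient (log-odds per exposure unit),
    with the normal-theory +/-1.96*SE interval. Degenerate outcomes and
    separation raise structured errors.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is degenerate (single class)")
    X = _design(exposure, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(
            "separation detected in logistic fit; a penalized fit is required") from err
    return MREstimate.from_beta_se("observational", fit.params[1], fit.bse[1],
                                   n_samples=int(y.size))


def iv_two_stage(outcome: np.ndarray, exposure: np.ndarray, score: np.ndarray,
                 covariates=None, second_stage: str = "logistic") -> MREstimate:
    """Two-stage IV estimate of the causal effect of exposure on outcome.

    Stage 1: OLS of exposure on score (+ covariates); Stage 2: logistic (or
    linear) regression of outcome on the stage-1 fitted exposure (+ the same
    covariates). The reported SE is the HC1 sandwich from the second stage.
    The univariate first-stage F is attached; F < 10 triggers a
    WeakInstrumentWarning.
    """
    s = np.asarray(score, dtype=float)
    if s.std() == 0:
        raise ValueError("score has zero variance; no first stage")
    X1 = _design(s, covariates)
    fit1 = sm.OLS(np.asarray(exposure, dtype=float), X1).fit()
    fitted = fit1.fittedvalues
    strength = instrument_strength(s, exposure, covariates)
    if strength.f_stat < 10:
        warnings.warn(f"first-stage F = {strength.f_stat:.2f} < 10; weak instrument",
                      WeakInstrumentWarning, stacklevel=2)

    X2 = _design(fitted, covariates)
    y = np.asarray(outcome, dtype=float)
    if second_stage == "logistic":
        if y.min() == y.max():
            raise ValueError("outcome is degenerate (single class)")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit2 = sm.Logit(y, X2).fit(disp=0, cov_type="HC1")
        except (PerfectSeparationError, np.linalg.LinAlgError) as err:
            raise SeparationError("separation in second-stage logistic fit") from err
        scale = "log_odds"
    elif second_stage == "linear":
        fit2 = sm.OLS(y, X2).fit(cov_type="HC1")
        scale = "linear"
    else:
        raise ValueError("second_stage must be 'logistic' or 'linear'")
    return MREstimate.from_beta_se("tsls", fit2.params[1], fit2.bse[1],
                                   scale=scale, n_samples=int(y.size),
                                   first_stage_f=strength.f_stat)


def sex_stratified(outcome: np.ndarray, exposure: np.ndarray, score: np.ndarray,
                   sex: np.ndarray, covariates=None,
                   method: str = "tsls") -> dict[int, MREstimate | None]:
    """Run the chosen estimator separately in each sex stratum.

    Returns ``{0: estimate, 1: estimate}``; a stratum whose outcome has a
    single class is returned as None (skipped with a warning) while an empty
    stratum raises :class:`StratumError`. The two entries feed the Fisher-z
    sex-difference test.
    """
    sex = np.asarray(sex)
    results: dict[int, MREstimate | None] = {}
    for stratum in (0, 1):
        mask = sex == stratum
        if not mask.any():
            raise StratumError(f"stratum sex={stratum} is empty")
        y = np.asarray(outcome)[mask]
        if np.unique(y).size < 2:
            warnings.warn(f"stratum sex={stratum} has a single outcome class; skipped",
                          stacklevel=2)
            results[stratum] = None
            continue
        cov = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            cov = C[mask] if C.ndim > 1 else C[mask]
        if method == "tsls":
            results[stratum] = iv_two_stage(y, np.asarray(exposure)[mask],
                                            np.asarray(score)[mask], cov)
        elif method == "observational":
            results[stratum] = observational_logistic(y, np.asarray(exposure)[mask], cov)
        else:
            raise ValueError("method must be 'tsls' or 'observational'")
    return results
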