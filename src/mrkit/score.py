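"""Weighted genetic risk scores, exposure transforms and instrument diagnostics.

The score follows the two-step construction used in biobank GRS analyses:
a weighted allele sum (weights = per-allele exposure effects from an external
GWAS) rescaled to the trait-increasing-allele-count scale,

    weighted score = sum_j beta_j g_j
    GRS            = weighted score * n_SNPs / sum_j beta_j

so that with equal weights the GRS is exactly the raw allele count. Also here:
the rank-based inverse-normal exposure transform, first-stage strength (R^2
and F), a confounder screen of the score, and BMI categorization into the
normal-weight / obese analysis groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import wald_p

__all__ = [
    "InstrumentSet",
    "StrengthResult",
    "weighted_grs",
    "inverse_normalize",
    "instrument_strength",
    "confounder_scan",
    "categorize_bmi",
    "read_instruments",
    "write_instruments",
]


@dataclass
class InstrumentSet:
    """Named variant set with exposure weights and per-variant subset labels."""

    table: pd.DataFrame  # snp, effect_allele, weight, subset_label

    def __post_init__(self) -> None:
        required = {"snp", "effect_allele", "weight", "subset_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"instrument table missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.table["weight"])):
            raise ValueError("instrument weights must be finite")

    @property
    def snps(self) -> list[str]:
        return list(self.table["snp"])

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    def subset(self, label: str) -> "InstrumentSet":
        sub = self.table[self.table["subset_label"] == label]
        if sub.empty:
            raise KeyError(f"no instruments labelled {label!r}")
        return InstrumentSet(sub.reset_index(drop=True))

    def labels(self) -> list[str]:
        return sorted(self.table["subset_label"].unique())

    @classmethod
    def from_true_parameters(cls, variant_ids, tp, neuronal_fraction: float = 43 / 73,
                             seed: int = 0) -> "InstrumentSet":
        """Instrument set using the generative exposure effects as weights.

        Subset labels split the variants into a 'neuronal'-like and a
        'non_neuronal'-like group (default split 43:30 out of 73) for
        over-identification contrasts.
        """
        rng = np.random.default_rng(seed)
        k = len(variant_ids)
        n_a = int(round(neuronal_fraction * k))
        labels = np.array(["non_neuronal"] * k, dtype=object)
        labels[rng.choice(k, size=n_a, replace=False)] = "neuronal"
        return cls(pd.DataFrame({
            "snp": list(variant_ids),
            "effect_allele": tp.effect_alleles if len(tp.effect_alleles) else "A",
            "weight": tp.alpha,
            "subset_label": labels,
        }))


def read_instruments(path: str | Path) -> InstrumentSet:
    return InstrumentSet(pd.read_csv(path, sep="\t"))


def write_instruments(instruments: InstrumentSet, path: str | Path) -> None:
    instruments.table.to_csv(path, sep="\t", index=False)


def weighted_grs(dosages: pd.DataFrame | np.ndarray, instruments: InstrumentSet,
                 variant_ids: list[str] | None = None) -> np.ndarray:
    """Rescaled weighted genetic risk score per sample.

    ``dosages`` is a DataFrame whose columns are variant IDs, or an ndarray
    with ``variant_ids`` naming its columns. All instrument variants must be
    present; the weight sum must be non-zero for the allele-count rescaling.
    """
    if isinstance(dosages, pd.DataFrame):
        frame = dosages
    else:
        if variant_ids is None:
            raise ValueError("variant_ids required with an ndarray dosage matrix")
        frame = pd.DataFrame(np.asarray(dosages), columns=list(variant_ids))
    missing = [s for s in instruments.snps if s not in frame.columns]
    if missing:
        raise KeyError(f"dosage matrix missing instrument variant(s): {missing}")
    w = instruments.weights
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("sum of instrument weights is zero; rescaling undefined")
    G = frame[instruments.snps].to_numpy(dtype=float)
    return (G @ w) * len(w) / wsum


def inverse_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((r - 0.5)/n).

    Ties receive average ranks (tied inputs map to equal outputs); missing
    values are preserved. The output has mean ~0 and SD ~1 and preserves the
    rank order of the input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    v = x[mask]
    if v.size < 2:
        raise ValueError("inverse_normalize needs at least 2 non-missing values")
    if np.all(v == v[0]):
        raise ValueError("inverse_normalize undefined for constant input")
    ranks = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / v.size)
    return out


@dataclass
class StrengthResult:
    r2: float
    f_stat: float
    n: int


def instrument_strength(score: np.ndarray, exposure: np.ndarray,
                        covariates: pd.DataFrame | np.ndarray | None = None) -> StrengthResult:
    """First-stage strength of a single score: R^2 and F.

    Score and exposure are residualized on the covariates (plus intercept)
    first; R^2 then comes from the simple regression of exposure on score and
    F = R^2 (n - 2) / (1 - R^2), the univariate first-stage F of a GRS
    analysis. Exact collinearity reports F = +inf.
    """
    s = np.asarray(score, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if s.shape != x.shape:
        raise ValueError("score and exposure must have the same length")
    n = s.size
    if n < 3:
        raise ValueError("instrument_strength needs at least 3 samples")
    if covariates is not None:
        C = sm.add_constant(np.asarray(covariates, dtype=float))
        s = s - C @ np.linalg.lstsq(C, s, rcond=None)[0]
        x = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    s = s - s.mean()
    x = x - x.mean()
    sxx = s @ s
    if sxx == 0:
        raise ValueError("score has zero variance")
    r2 = float((s @ x) ** 2 / (sxx * (x @ x)))
    f = np.inf if r2 >= 1.0 else r2 * (n - 2) / (1.0 - r2)
    return StrengthResult(r2=r2, f_stat=float(f), n=n)


def confounder_scan(score: np.ndarray, covariates: pd.DataFrame,
                    exposure: np.ndarray) -> pd.DataFrame:
    """Regress each covariate on the score, with and without exposure adjustment.

    A score built from valid instruments should show null associations with
    pre-exposure confounders; associations that vanish on exposure adjustment
    point at traits downstream of the exposure rather than confounders.
    Constant covariates are skipped with a note.
    """
    s = np.asarray(score, dtype=float)
    x = np.asarray(exposure, dtype=float)
    rows = []
    for name in covariates.columns:
        c = covariates[name].to_numpy(dtype=float)
        if np.nanstd(c) == 0:
            rows.append({"covariate": name, "note": "constant; skipped"})
            continue
        fit_u = sm.OLS(c, sm.add_constant(s)).fit()
        fit_a = sm.OLS(c, sm.add_constant(np.column_stack([s, x]))).fit()
        rows.append({
            "covariate": name,
            "beta_unadj": fit_u.params[1], "se_unadj": fit_u.bse[1],
            "p_unadj": wald_p(fit_u.params[1], fit_u.bse[1]),
            "beta_adj": fit_a.params[1], "se_adj": fit_a.bse[1],
            "p_adj": wald_p(fit_a.params[1], fit_a.bse[1]),
            "note": "",
        })
    cols = ["covariate", "beta_unadj", "se_unadj", "p_unadj",
            "beta_adj", "se_adj", "p_adj", "note"]
    return pd.DataFrame(rows).reindex(columns=cols)


def categorize_bmi(values: np.ndarray) -> np.ndarray:
    """Classify BMI (kg/m^2) into 'normal' (18.5-24.9), 'obese' (>30), 'excluded'.

    The excluded band covers underweight (<18.5) and overweight-but-not-obese
    (25-30) individuals, matching a normal-weight vs obese case-control
    contrast. Values outside (10, 80) are rejected as probable unit errors.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative BMI value")
    if np.any((v <= 10) | (v >= 80)):
        raise ValueError("BMI outside (10, 80) kg/m^2; check units")
    out = np.full(v.shape, "excluded", dtype=object)
    out[(v >= 18.5) & (v <= 24.9)] = "normal"
    out[v > 30] = "obese"
    return out
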