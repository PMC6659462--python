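"""GWAS summary-statistic tables: reading, validation, harmonization, writing.

Two-sample MR regresses variant-outcome effects on variant-exposure effects,
which is only meaningful once both refer to the same effect allele. This
module provides a strict reader for tab-separated GWAS tables (remappable
column names), row-level validation with line numbers, and an allele
harmonizer that resolves swapped alleles, strand flips, and palindromic
(A/T, C/G) ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatsError",
    "HarmonizationError",
    "DEFAULT_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "validate_records",
    "harmonize",
]


class SummaryStatsError(ValueError):
    """File-level failure reading or validating a summary-statistic table."""


class HarmonizationError(ValueError):
    """No variants survive harmonization."""


# canonical column set of the on-disk dialect
DEFAULT_COLUMNS = {
    "snp": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = set(_COMPLEMENT)


@dataclass
class RowError:
    line: int
    snp: str
    reason: str


@dataclass
class ValidationReport:
    n_read: int = 0
    errors: list[RowError] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.errors],
                            columns=["line", "snp", "reason"])


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Enforce the per-record invariants; return (clean rows, report).

    Rejected rows are reported with their 1-based data line number and a
    reason string; they are removed from the returned frame.
    """
    report = ValidationReport(n_read=len(df))
    reasons = pd.Series("", index=df.index, dtype=object)

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    bad_allele = ~(ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES))
    reasons[bad_allele & (reasons == "")] = "invalid allele"
    same_allele = (ea == oa) & ~bad_allele
    reasons[same_allele & (reasons == "")] = "identical alleles"

    num = df[["eaf", "beta", "se", "pval", "n"]].apply(pd.to_numeric, errors="coerce")
    reasons[num.isna().any(axis=1) & (reasons == "")] = "unparseable numeric"
    reasons[(num["se"] <= 0) & (reasons == "")] = "nonpositive SE"
    reasons[((num["eaf"] <= 0) | (num["eaf"] >= 1)) & (reasons == "")] = "eaf outside (0,1)"
    reasons[((num["pval"] <= 0) | (num["pval"] > 1)) & (reasons == "")] = "p outside (0,1]"
    reasons[(num["n"] <= 0) & (reasons == "")] = "nonpositive n"

    bad = reasons != ""
    for idx in df.index[bad]:
        report.errors.append(RowError(line=int(idx) + 1,
                                      snp=str(df.at[idx, "snp"]),
                                      reason=reasons[idx]))
    clean = df.loc[~bad].copy()
    clean["effect_allele"] = ea[~bad]
    clean["other_allele"] = oa[~bad]
    for c in ("eaf", "beta", "se", "pval"):
        clean[c] = num.loc[~bad, c]
    clean["n"] = num.loc[~bad, "n"].astype(np.int64)
    return clean.reset_index(drop=True), report


def read_summary_stats(
    path: str | Path,
    columns: dict[str, str] | None = None,
    max_bad_fraction: float = 0.05,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a tab-separated GWAS summary-statistic table.

    ``columns`` maps canonical field names (keys of DEFAULT_COLUMNS) to the
    column names in the file. Raises :class:`SummaryStatsError` when a
    required column is absent or when more than ``max_bad_fraction`` of rows
    fail validation; otherwise bad rows are collected in the returned report.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise SummaryStatsError(f"{path}: missing required column(s) {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})[list(colmap)]
    clean, report = validate_records(df)
    if report.n_read and len(report.errors) / report.n_read > max_bad_fraction:
        raise SummaryStatsError(
            f"{path}: {len(report.errors)}/{report.n_read} rows failed validation "
            f"(limit {max_bad_fraction:.0%}); first: line {report.errors[0].line} "
            f"{report.errors[0].reason}")
    return clean, report


def write_summary_stats(df: pd.DataFrame, path: str | Path,
                        columns: dict[str, str] | None = None) -> None:
    """Write records in the tab-separated dialect (round-trips with the reader)."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    out = df.rename(columns=colmap)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effects to the exposure effect allele.

    Returns ``(pairs, audit)``: ``pairs`` has one row per surviving variant
    with columns snp, effect_allele, other_allele, bx, se_x, by, se_y,
    eaf_exposure, eaf_outcome, flag; ``audit`` records every dropped variant
    with a reason. Resolution rules, applied on the shared variant IDs:

    * same alleles -> unchanged;
    * swapped alleles -> by negated, outcome eaf complemented (allele_swap);
    * strand-complement alleles -> relabelled (strand_flip), possibly also
      swapped;
    * palindromic variants (A/T or C/G): dropped when the outcome eaf is
      within ``palindrome_eaf_window`` of 0.5, else aligned by frequency;
    * anything else -> dropped as irreconcilable.
    """
    exp = exposure.set_index("snp" if "snp" in exposure.columns else "SNP", drop=False)
    out = outcome.set_index("snp" if "snp" in outcome.columns else "SNP", drop=False)
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise HarmonizationError("no shared variant IDs between exposure and outcome")

    rows, audit = [], []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        by, eaf_y = float(o["beta"]), float(o["eaf"])
        flags: list[str] = []

        if _is_palindromic(e_ea, e_oa):
            if {o_ea, o_oa} != {e_ea, e_oa}:
                audit.append({"snp": snp, "reason": "irreconcilable alleles"})
                continue
            if abs(eaf_y - 0.5) <= palindrome_eaf_window:
                audit.append({"snp": snp, "reason": "palindromic near eaf 0.5"})
                rows_flag = "dropped_palindromic"
                audit[-1]["flag"] = rows_flag
                continue
            # align by frequency: both eafs must sit on the same side of 0.5
            if (float(e["eaf"]) - 0.5) * (eaf_y - 0.5) < 0:
                by, eaf_y = -by, 1.0 - eaf_y
                flags.append("allele_swap")
        else:
            if (o_ea, o_oa) == (e_ea, e_oa):
                pass
            elif (o_ea, o_oa) == (e_oa, e_ea):
                by, eaf_y = -by, 1.0 - eaf_y
                flags.append("allele_swap")
            elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (e_ea, e_oa):
                flags.append("strand_flip")
            elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (e_oa, e_ea):
                by, eaf_y = -by, 1.0 - eaf_y
                flags.extend(["strand_flip", "allele_swap"])
            else:
                audit.append({"snp": snp, "reason": "irreconcilable alleles"})
                continue

        rows.append({
            "snp": snp,
            "effect_allele": e_ea,
            "other_allele": e_oa,
            "bx": float(e["beta"]), "se_x": float(e["se"]),
            "by": by, "se_y": float(o["se"]),
            "eaf_exposure": float(e["eaf"]), "eaf_outcome": eaf_y,
            "flag": "|".join(flags) if flags else "unchanged",
        })

    if not rows:
        raise HarmonizationError("zero variants survived harmonization")
    pairs = pd.DataFrame(rows)
    audit_df = pd.DataFrame(audit, columns=["snp", "reason", "flag"])
    return pairs, audit_df
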