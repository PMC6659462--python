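"""Config-driven orchestration of the full MR analysis plan.

One configuration (YAML or :class:`AnalysisConfig`) fully specifies a run:
either a simulation block or input paths. The pipeline then sequences
GRS construction -> confounder screen -> observational models -> one-sample
IV (overall and by sex) -> per-variant scans, harmonization and two-sample
estimators -> instrument-subset over-identification -> pleiotropy screen ->
negative controls -> replication + meta-analysis, writing one tab-separated
table per stage plus a manifest with the seed, versions, config hash and
per-table content hashes. Reruns with the same config are bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (compare_estimates, meta_fixed, negative_control_battery,
                        overidentification_test, pleiotropy_screen)
from .onesample import MREstimate, iv_two_stage, observational_logistic, sex_stratified
from .score import (InstrumentSet, categorize_bmi, confounder_scan,
                    instrument_strength, weighted_grs, write_instruments)
from .sumstats import harmonize, write_summary_stats
from .synthetic import (CohortTable, SimulationConfig, cohort_to_summary_stats,
                        read_cohort, simulate_cohort, write_cohort)
from .twosample import egger, ivw, weighted_median
from .worked import worked_examples

__all__ = ["AnalysisConfig", "StageError", "run_pipeline"]

log = logging.getLogger("mrkit.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Full specification of one pipeline run.

    Exactly one of ``simulation`` or ``cohort_path`` must be set. With a
    cohort path, ``instrument_path`` must point at a tab-separated instrument
    file (snp, effect_allele, weight, subset_label).
    """

    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    instrument_path: str | None = None
    methods: tuple[str, ...] = ("ivw_fixed", "ivw_random", "egger",
                                "weighted_median", "penalized_weighted_median")
    outdir: str = "results/pipeline"
    seed: int = 2019
    bootstrap_reps: int = 500
    replication_fraction: float = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.cohort_path is None):
            raise ValueError("exactly one of simulation / cohort_path must be given")
        if self.cohort_path is not None and self.instrument_path is None:
            raise ValueError("instrument_path required when loading a cohort")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimulationConfig(**sim)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def _est_row(label: str, stratum: str, est: MREstimate | None) -> dict:
    if est is None:
        return {"analysis": label, "stratum": stratum, "note": "skipped"}
    d = {"analysis": label, "stratum": stratum, "note": ""}
    d.update({k: v for k, v in est.to_dict().items() if v is not None})
    return d


class _Runner:
    """Internal stage sequencer; collects tables and timing."""

    def __init__(self, config: AnalysisConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.tables: dict[str, Path] = {}
        self.timings: dict[str, float] = {}

    def stage(self, name: str, fn, *args, **kw):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            out = fn(*args, **kw)
        except Exception as err:  # noqa: BLE001 - converted to structured error
            (self.outdir / "FAILED").write_text(f"{name}: {err}\n")
            raise StageError(name, err) from err
        self.timings[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", name, self.timings[name])
        return out

    def save(self, name: str, df: pd.DataFrame) -> None:
        path = self.outdir / f"{name}.tsv"
        _write(df, path)
        self.tables[name] = path


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis plan; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    r = _Runner(config)
    failed_marker = r.outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    # ---- data -------------------------------------------------------------
    if config.simulation is not None:
        cohort, tp = r.stage("simulate", simulate_cohort, config.simulation)
        instruments = InstrumentSet.from_true_parameters(
            cohort.variant_ids, tp, seed=config.seed)
        if cohort.n_samples <= 5000:  # keep bundles small at biobank n
            write_cohort(cohort, r.outdir / "cohort.tsv")
        write_instruments(instruments, r.outdir / "instruments.tsv")
        case_fraction = config.simulation.case_fraction
    else:
        cohort = r.stage("load", read_cohort, config.cohort_path)
        from .score import read_instruments
        instruments = read_instruments(config.instrument_path)
        case_fraction = float(np.mean(cohort.outcome))

    # ---- genetic risk score ----------------------------------------------
    def grs_stage():
        score = weighted_grs(cohort.dosage_frame(), instruments)
        strength = instrument_strength(score, cohort.exposure)
        report = pd.DataFrame([{
            "n_snps": len(instruments.snps),
            "r2": strength.r2,
            "f_stat": strength.f_stat,
            "n": strength.n,
        }])
        scan = confounder_scan(score, cohort.covariates, cohort.exposure)
        return score, report, scan

    score, grs_report, conf_scan = r.stage("grs", grs_stage)
    r.save("grs_report", grs_report)
    r.save("confounder_scan", conf_scan)

    # ---- observational + one-sample IV, overall and by sex ---------------
    def onesample_stage():
        rows = []
        obs = observational_logistic(cohort.outcome, cohort.exposure)
        tsls = iv_two_stage(cohort.outcome, cohort.exposure, score)
        rows += [_est_row("observational", "all", obs), _est_row("tsls", "all", tsls)]
        for method in ("observational", "tsls"):
            strata = sex_stratified(cohort.outcome, cohort.exposure, score,
                                    cohort.sex, method=method)
            for sx, est in strata.items():
                rows.append(_est_row(method, {0: "men", 1: "women"}[sx], est))
            if strata[0] is not None and strata[1] is not None:
                comp = compare_estimates(strata[1], strata[0], "women", "men")
                rows.append({"analysis": f"{method}_sex_difference", "stratum": "contrast",
                             "estimate": comp.estimate_a.beta - comp.estimate_b.beta,
                             "p": comp.p_difference, "note": f"z={comp.z:.4f}"})
        # genetically instrumented obesity: map exposure onto a BMI-like scale
        bmi = 27.4 + 4.7 * cohort.exposure
        bmi = np.clip(bmi, 10.5, 79.5)
        cats = categorize_bmi(bmi)
        keep = cats != "excluded"
        if np.unique(cohort.outcome[keep]).size == 2:
            obese = (cats[keep] == "obese").astype(float)
            tsls_ob = iv_two_stage(cohort.outcome[keep], obese, score[keep])
            rows.append(_est_row("tsls_obesity", "all", tsls_ob))
        return pd.DataFrame(rows)

    onesample_table = r.stage("one_sample", onesample_stage)
    r.save("onesample", onesample_table)

    # ---- per-variant scans, harmonization, two-sample estimators ----------
    def scans_stage():
        exp_stats = cohort_to_summary_stats(cohort, "exposure")
        out_stats = cohort_to_summary_stats(cohort, "outcome")
        write_summary_stats(exp_stats, r.outdir / "exposure_gwas.tsv")
        write_summary_stats(out_stats, r.outdir / "outcome_gwas.tsv")
        exp = exp_stats.rename(columns={"SNP": "snp"})
        out = out_stats.rename(columns={"SNP": "snp"})
        pairs, audit = harmonize(exp, out)
        return exp, pairs, audit

    exp_stats, pairs, audit = r.stage("harmonize", scans_stage)
    r.save("harmonization_audit", audit if not audit.empty
           else pd.DataFrame(columns=["snp", "reason", "flag"]))
    r.save("harmonized_pairs", pairs)

    def twosample_stage():
        rows = []
        if len(pairs) < 3 and ("egger" in config.methods):
            raise ValueError("MR-Egger requires >=3 pairs (harmonized set too small)")
        if "ivw_fixed" in config.methods:
            est, _ = ivw(pairs, "fixed")
            rows.append(_est_row("ivw_fixed", "all", est))
        if "ivw_random" in config.methods:
            est, _ = ivw(pairs, "random")
            rows.append(_est_row("ivw_random", "all", est))
        if "egger" in config.methods:
            slope, intercept = egger(pairs)
            rows.append(_est_row("egger_slope", "all", slope))
            rows.append(_est_row("egger_intercept", "all", intercept))
        if "weighted_median" in config.methods:
            rows.append(_est_row("weighted_median", "all", weighted_median(
                pairs, penalized=False, bootstrap_reps=config.bootstrap_reps,
                seed=config.seed)))
        if "penalized_weighted_median" in config.methods:
            rows.append(_est_row("penalized_weighted_median", "all", weighted_median(
                pairs, penalized=True, bootstrap_reps=config.bootstrap_reps,
                seed=config.seed)))
        return pd.DataFrame(rows)

    twosample_table = r.stage("two_sample", twosample_stage)
    r.save("twosample", twosample_table)

    # scatter export: the per-variant points of the two-sample fits
    r.save("scatter_data", pairs[["snp", "bx", "se_x", "by", "se_y"]])

    # ---- instrument subsets (over-identification) --------------------------
    def subsets_stage():
        labels = instruments.labels()
        if len(labels) < 2:
            return pd.DataFrame([{"note": "single subset; contrast skipped"}])
        a, b = labels[0], labels[1]
        snps_a = set(instruments.subset(a).snps)
        snps_b = set(instruments.subset(b).snps)
        pa = pairs[pairs["snp"].isin(snps_a)]
        pb = pairs[pairs["snp"].isin(snps_b)]
        comp = overidentification_test(pa, pb, a, b)
        return pd.DataFrame([{
            "subset_a": a, "estimate_a": comp.estimate_a.beta, "se_a": comp.estimate_a.se,
            "subset_b": b, "estimate_b": comp.estimate_b.beta, "se_b": comp.estimate_b.se,
            "z": comp.z, "p_difference": comp.p_difference,
        }])

    r.save("subset_comparison", r.stage("subsets", subsets_stage))

    # ---- pleiotropy screen -------------------------------------------------
    r.save("pleiotropy_screen",
           r.stage("screen", pleiotropy_screen, pairs, case_fraction))

    # ---- negative controls -------------------------------------------------
    def controls_stage():
        return negative_control_battery(cohort.controls, cohort.exposure, score,
                                        cohort.covariates["sep"].to_numpy())

    r.save("negative_controls", r.stage("negative_controls", controls_stage))

    # ---- replication cohort + meta-analysis --------------------------------
    def meta_stage():
        est_main, _ = ivw(pairs, "fixed")
        if config.simulation is None:
            return pd.DataFrame([_est_row("ivw_fixed", "single_study", est_main)])
        repl_cfg = dataclasses.replace(
            config.simulation,
            n_samples=max(1000, int(config.simulation.n_samples * config.replication_fraction)),
            seed=int(np.random.SeedSequence([config.seed, 77]).generate_state(1)[0] % 2**31))
        repl_cohort, _ = simulate_cohort(repl_cfg)
        repl_out = cohort_to_summary_stats(repl_cohort, "outcome").rename(columns={"SNP": "snp"})
        repl_pairs, _ = harmonize(exp_stats, repl_out)
        est_repl, _ = ivw(repl_pairs, "fixed")
        pooled, het = meta_fixed([est_main, est_repl])
        return pd.DataFrame([
            _est_row("ivw_fixed", "discovery", est_main),
            _est_row("ivw_fixed", "replication", est_repl),
            _est_row("meta_fixed", "pooled", pooled),
        ])

    r.save("meta", r.stage("meta", meta_stage))

    # ---- worked examples + table-shaped summaries --------------------------
    r.save("worked_examples", r.stage("worked_examples", worked_examples))
    r.save("summary_main", _summary_main(onesample_table, twosample_table))

    # ---- manifest ----------------------------------------------------------
    table_hashes = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(r.tables.items())
    }
    manifest = {
        "mrkit_version": __version__,
        "versions": {m.__name__: m.__version__ for m in
                     (np, pd, __import__("scipy"), __import__("statsmodels"))},
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "tables": {k: str(v) for k, v in r.tables.items()},
        "table_hashes": table_hashes,
        "stage_seconds": {k: round(v, 3) for k, v in r.timings.items()},
    }
    with open(r.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _summary_main(onesample: pd.DataFrame, twosample: pd.DataFrame) -> pd.DataFrame:
    """Main-results-shaped summary: observational / genetic / Egger per stratum."""
    rows = []
    for stratum in ("all", "men", "women"):
        row = {"stratum": stratum}
        for label, tag in (("observational", "observational"),
                           ("tsls", "genetic")):
            hit = onesample[(onesample["analysis"] == label)
                            & (onesample["stratum"] == stratum)]
            if not hit.empty and "estimate" in hit.columns and np.isfinite(
                    hit.iloc[0].get("estimate", np.nan)):
                h = hit.iloc[0]
                row[f"{tag}_or"] = float(np.exp(h["estimate"]))
                row[f"{tag}_ci"] = f"({np.exp(h['ci_low']):.3f}, {np.exp(h['ci_high']):.3f})"
                row[f"{tag}_p"] = h["p"]
        if stratum == "all" and not twosample.empty:
            hit = twosample[twosample["analysis"] == "egger_slope"]
            if not hit.empty:
                h = hit.iloc[0]
                row["egger_or"] = float(np.exp(h["estimate"]))
                row["egger_ci"] = f"({np.exp(h['ci_low']):.3f}, {np.exp(h['ci_high']):.3f})"
                row["egger_p"] = h["p"]
        rows.append(row)
    return pd.DataFrame(rows)
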