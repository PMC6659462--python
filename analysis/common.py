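"""Shared analysis conditions for the numbered drivers.

One synthetic biobank-style cohort underlies the whole analysis sequence:
73 instrument variants explaining 1.7% of the exposure variance, causal
log-odds 0.166 per SD exposure (OR 1.18), case fraction 0.144, moderate
confounding. n = 50 000 keeps every driver interactive while leaving all
estimates comfortably resolvable.
"""

from pathlib import Path

from mrkit.score import InstrumentSet, weighted_grs
from mrkit.synthetic import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

COHORT_CONFIG = SimulationConfig(n_samples=50_000, seed=2019)

_cache = {}


def get_cohort(config: SimulationConfig = COHORT_CONFIG):
    if config not in _cache:
        _cache[config] = simulate_cohort(config)
    return _cache[config]


def get_scored(config: SimulationConfig = COHORT_CONFIG):
    cohort, tp = get_cohort(config)
    instruments = InstrumentSet.from_true_parameters(cohort.variant_ids, tp,
                                                     seed=config.seed)
    score = weighted_grs(cohort.dosage_frame(), instruments)
    return cohort, tp, instruments, score


def save(df, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
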