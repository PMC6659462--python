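import dataclasses

import numpy as np
import pandas as pd
import pytest

from mrkit.score import InstrumentSet, weighted_grs
from mrkit.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort100k():
    """Analysis-condition cohort at n=100 000 (73 variants, R^2=1.7%)."""
    cfg = SimulationConfig(n_samples=100_000, seed=11)
    cohort, tp = simulate_cohort(cfg)
    return cfg, cohort, tp


@pytest.fixture(scope="session")
def scored100k(cohort100k):
    cfg, cohort, tp = cohort100k
    instruments = InstrumentSet.from_true_parameters(cohort.variant_ids, tp, seed=11)
    score = weighted_grs(cohort.dosage_frame(), instruments)
    return cfg, cohort, tp, instruments, score


@pytest.fixture(scope="session")
def confounded_null_cohort():
    """theta=0 but strong confounding: the observational model should be biased."""
    cfg = SimulationConfig(n_samples=100_000, causal_effect=0.0,
                           confounder_effect_x=0.3, confounder_effect_y=0.4, seed=13)
    cohort, tp = simulate_cohort(cfg)
    return cfg, cohort, tp


def make_pairs(bx, by, se_y, se_x=None, snps=None):
    bx = np.asarray(bx, dtype=float)
    k = bx.size
    return pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{j}" for j in range(k)],
        "bx": bx,
        "se_x": np.broadcast_to(se_x if se_x is not None else 1e-6, k).astype(float),
        "by": np.asarray(by, dtype=float),
        "se_y": np.broadcast_to(se_y, k).astype(float),
    })


@pytest.fixture
def pairs_factory():
    return make_pairs


def replicate_configs(base: SimulationConfig, n_reps: int, seed0: int):
    return [dataclasses.replace(base, seed=seed0 + r) for r in range(n_reps)]
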