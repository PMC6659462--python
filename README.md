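# mrkit — Mendelian-randomization analysis toolkit

`mrkit` implements, end to end, the analysis plan of a biobank-scale
Mendelian-randomization (MR) study of adiposity and depression: weighted
genetic risk scores (GRS), one-sample two-stage instrumental-variable
estimation for binary outcomes, the two-sample summary-statistic estimators
(IVW, MR-Egger, weighted and penalized weighted median), allele
harmonization, pleiotropy and stratification diagnostics, sex-difference and
over-identification contrasts, and fixed-effect meta-analysis. A synthetic
cohort generator reproduces the statistical structure of such a study —
Hardy–Weinberg genotypes, a confounded exposure whose instrument explains a
calibrated 1.7% of variance, a logistic outcome with ~14% case fraction,
optional pleiotropy and sex-specific effects, and confounder-driven
negative-control traits — so every stage is testable without any data
download.

It is written for epidemiologists and biostatisticians who want a
transparent, tested reference implementation of these methods, and for
anyone who needs a generative benchmark with known ground truth to study MR
estimator behaviour.

## The model in brief

Genetic variants `G_j` are used as instruments for an exposure `X`
(in SD units) on a binary outcome `Y`. One-sample, with individual data:

```
stage 1:  X  = a + b·GRS + e,        GRS = (Σ_j β_j g_j) · n / Σ_j β_j
stage 2:  logit P(Y=1) = c + θ·X̂    (HC1 robust SEs)
```

Two-sample, with per-variant summary statistics `(bx_j, by_j)`:

```
IVW:     θ̂ = Σ w_j bx_j by_j / Σ w_j bx_j²,   w_j = 1/se_yj²
Egger:   by_j = θ₀ + θ₁ bx_j  (weighted, free intercept; bx_j > 0)
median:  weighted 50% point of the ratios by_j/bx_j, w_j = bx_j²/se_yj²
```

θ is the causal log-odds of the outcome per 1-SD exposure; `exp(θ)` the
odds ratio. Because the second stage is logistic, recovery tests target the
*marginal* estimand θ\*, computed once per configuration by running the
two-stage estimator on a 2×10⁶-sample oracle cohort (see
`docs/methods.md`).

## Worked example

```python
import numpy as np
from mrkit import (SimulationConfig, simulate_cohort, cohort_to_summary_stats,
                   InstrumentSet, weighted_grs, instrument_strength,
                   iv_two_stage, observational_logistic, harmonize, ivw)

cfg = SimulationConfig(n_samples=50_000, seed=2019)   # theta=0.166, R^2=1.7%
cohort, truth = simulate_cohort(cfg)

inst = InstrumentSet.from_true_parameters(cohort.variant_ids, truth, seed=2019)
score = weighted_grs(cohort.dosage_frame(), inst)
print(instrument_strength(score, cohort.exposure))
# StrengthResult(r2=0.01582..., f_stat=804.08..., n=50000)

obs = observational_logistic(cohort.outcome, cohort.exposure)
iv = iv_two_stage(cohort.outcome, cohort.exposure, score)
print(round(obs.odds_ratio, 3), round(iv.odds_ratio, 3), round(iv.p, 3))
# 1.317 1.266 0.021

exp = cohort_to_summary_stats(cohort, "exposure").rename(columns={"SNP": "snp"})
out = cohort_to_summary_stats(cohort, "outcome").rename(columns={"SNP": "snp"})
pairs, audit = harmonize(exp, out)
est, het = ivw(pairs, "fixed")
print(round(np.exp(est.estimate), 3), round(het.p_q, 2))
# 1.353 0.43
```

The observational OR (1.317) overstates the causal one because the cohort
is confounded by construction; the IV estimates (one-sample 1.266,
two-sample IVW 1.353) bracket the oracle marginal estimand
(`exp(0.161) ≈ 1.175` for this configuration) within their sampling error,
and Cochran's Q finds no heterogeneity among the 73 per-variant estimates —
as it should, since no pleiotropy was simulated.

## Analysis drivers

The `analysis/` directory sequences the full study narrative as numbered
scripts, each writing tidy tables under `results/analysis/`:

```
python analysis/01_simulate_cohort.py        # generator checks
python analysis/02_genetic_risk_scores.py    # GRS strength + confounder screen
python analysis/03_one_sample_mr.py          # observational vs 2SLS, sex strata
python analysis/04_two_sample_mr.py          # scans, harmonization, IVW/Egger/median, meta
python analysis/05_pleiotropy_and_subsets.py # screen + over-identification
python analysis/06_negative_controls.py      # stratification diagnostics
python analysis/07_worked_examples.py        # published numbers from printed inputs
```

The same sequence is available as a single config-driven run
(`mrkit run-all --seed 2019 --out results/pipeline`), plus calculator-style
subcommands (`mrkit worked-examples`, `mrkit meta --estimate 0.2:0.1 ...`,
`mrkit mr-twosample --exposure exp.tsv --outcome out.tsv`, ...).

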