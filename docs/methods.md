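# Methods

`mrkit` re-implements, as a tested pipeline, the analysis plan of a
one-sample + two-sample Mendelian-randomization (MR) study of a continuous
adiposity exposure (BMI, analysed in SD units) on a binary depression
outcome, together with a synthetic cohort generator that reproduces the
statistical structure such an analysis assumes. This note records the
models, the defaults and why, the numerical choices, and what the synthetic
results do and do not establish.

## Generative model

For `n_samples` individuals and `n_variants` biallelic variants:

* **Genotypes.** Dosages `g_ij ~ Binomial(2, f_j)` i.i.d. across samples
  (Hardy–Weinberg proportions, no linkage disequilibrium), with allele
  frequencies `f_j ~ U(maf_lo, maf_hi)`, default U(0.05, 0.5).
* **Exposure.** `X = Σ_j α_j (g_ij − 2 f_j) + c_x U + σ ε`, with
  `U, ε ~ N(0,1)` independent. The per-variant effects `α_j` are half-normal
  draws rescaled so that `Σ_j 2 f_j (1−f_j) α_j² = target_r2` *exactly*
  (checked to 1e-9), and `σ² = 1 − target_r2 − c_x²`, so X has theoretical
  unit variance and the weighted score built from the `α_j` explains exactly
  `target_r2` of it. Default `target_r2 = 0.017`, the instrument strength of
  a 73-variant adult-BMI score (a 14-variant favourable-adiposity-style weak
  instrument corresponds to `target_r2 = 0.002`).
* **Outcome.** `logit P(Y=1) = β₀ + θ·m(sex)·X + Σ_j δ_j g_ij + c_y U`,
  where `m(sex)` multiplies the causal log-odds by `sex_effect_modifier` in
  the female stratum. `β₀` is solved by bracketed bisection on the simulated
  linear predictors so that the expected prevalence equals `case_fraction`
  (tolerance 1e-6 on the root; realized prevalence then matches to sampling
  error, < 0.005 at n = 100 000). Defaults: `θ = 0.166` (OR 1.18 per SD),
  `case_fraction = 41 397/287 503 ≈ 0.144` — the case/control ratio of the
  unrelated-individuals analysis the generator emulates.
* **Pleiotropy.** A fraction of variants receives direct outcome effects
  `δ_j`: half-normal with common sign (`directional`) or mean-zero normal
  (`balanced`), scaled by `pleiotropy_scale` (log-odds per allele).
* **Confounding.** Defaults `c_x = 0.3`, `c_y = 0.4`: strong enough that the
  observational estimate of a null causal effect is biased by several
  standard errors at biobank n, which is what makes the IV/observational
  contrast informative.
* **Covariates and negative controls.** The cohort carries a noisy
  confounder proxy, a centre-like categorical factor, a
  socioeconomic-position-like variable `sep = 0.8 U + s·G + 0.6 ε'` (where
  `G` is the standardized genetic-score axis and `s = stratification_effect`)
  and a trait downstream of the exposure. The negative-control traits (one
  continuous, one binary) are driven by `sep` only — hence by the confounder
  and, when `s ≠ 0`, by genotype — and never by X. `s ≠ 0` emulates residual
  population stratification along the score axis: it produces a spurious IV
  association with the controls that adjusting for `sep` attenuates, the
  diagnostic signature the negative-control battery is designed to show.

Sub-streams for frequencies, effects, genotypes, noise, etc. are derived
deterministically from the single root seed, so every artefact is
bit-reproducible and the frequencies used by `calibrate_effects` and
`simulate_genotypes` agree by construction.

## The oracle estimand θ\*

With a logistic second stage the IV estimand is a *marginal* log-odds ratio,
which differs from the conditional `θ` in the generative model even without
confounding (non-collapsibility). Rather than rely on approximation
formulas, `oracle_estimand` runs the package's own two-stage estimator once
per configuration on a single 2×10⁶-sample cohort drawn from the same
generative law (dedicated seed stream, cached). Recovery tests compare
against this θ\*; at OR ≈ 1.18 the attenuation is small (θ\* ≈ 0.161 vs
θ = 0.166) but not negligible relative to Monte-Carlo precision.

## Estimators

* **Observational:** maximum-likelihood logistic regression of outcome on
  exposure (optionally covariate-adjusted).
* **One-sample IV:** stage 1, OLS of exposure on the GRS (+ covariates,
  entered in both stages when supplied); stage 2, logistic (or linear)
  regression of the outcome on the stage-1 fitted values. SEs are HC1
  sandwich ("robust standard errors"); HC1 is the common default of the
  econometric software this procedure originates from. No control-function
  residual is added — the procedure is the plain two-stage one. The
  first-stage F is reported as `R²(n−2)/(1−R²)` from the univariate score
  regression; F < 10 warns.
* **GRS:** `score = (Σ β_j g_j) · n_SNPs / Σ β_j` — the weighted allele sum
  rescaled to the trait-increasing-allele-count scale, so equal weights give
  exactly the raw allele count.
* **Inverse-normal transform:** rank-based, `Φ⁻¹((r−0.5)/n)` with average
  ranks for ties (no Blom-style offset; the choice is documented rather than
  consequential at biobank n).
* **IVW:** weighted regression of `by` on `bx` through the origin, weights
  `1/se_y²`; fixed-effect SE `(Σ w bx²)^{-1/2}`; the random-effects variant
  uses multiplicative overdispersion `max(1, √(Q/(k−1)))` rather than an
  additive τ², matching the usual summary-MR convention.
* **MR-Egger:** weighted regression with free intercept after reorienting
  all pairs to `bx > 0` (the estimator is not orientation-invariant without
  this rule). SEs use multiplicative overdispersion floored at 1. The
  intercept estimates average directional pleiotropy; its p-value is the
  pleiotropy diagnostic.
* **Weighted median:** ratios `r_j = by_j/bx_j` with weights
  `w_j = bx_j²/se_y_j²`; the estimate interpolates the weighted empirical
  CDF at 0.5. The penalized variant multiplies `w_j` by `min(1, 20 q_j)`
  with `q_j` the upper χ²₁ tail of variant j's contribution to Cochran's Q
  about the unpenalized median (penalty constant 20 from the originating
  construction). SE by seeded parametric bootstrap (default 1000 reps)
  resampling `(bx_j, by_j)` from normals with their reported SEs.
* **Harmonization:** variant matching by ID; allele swap negates `by` and
  complements the outcome EAF; strand complements are relabelled;
  palindromic (A/T, C/G) variants are dropped when the outcome EAF is within
  0.08 of 0.5 (configurable), otherwise frequency-aligned.
* **Auxiliary inference:** Wald p from printed estimate+CI via
  `SE = (hi−lo)/(2·1.96)` (1.96, not 1.959964 — this is what reproduces
  printed p-values from printed intervals); Fisher z
  `(β₁−β₂)/√(SE₁²+SE₂²)` for sex and subset contrasts; fixed-effect
  inverse-variance meta-analysis with Cochran's Q (fixed-effect by default
  because the emulated analyses report no heterogeneity; a random-effects
  pooled estimate can be formed from the same pieces); per-variant
  pleiotropy screen converting outcome log-odds to SD units by
  `√(c(1−c))` with `c` the case fraction (the constant is configurable —
  published conversions differ in detail) and flagging
  `|by_SD| > |bx|`.
* **Over-identification:** IVW per disjoint instrument subset and a Fisher-z
  contrast of the two estimates (an estimate-difference test, not the
  Sargan/ivprobit machinery of the original software stack).

## Numerical and design choices

* All 95% intervals use ±1.96·SE; all p-values are two-sided normal unless
  a χ² statistic is involved.
* Per-variant scans of a cohort are vectorized: closed-form simple linear
  regression for continuous traits, and a damped 2-parameter Newton solver
  (one intercept+slope system per variant, solved jointly across variants)
  for binary traits, cross-checked against a reference logistic fit in the
  unit tests. Monomorphic variants are flagged, never dropped silently.
* Degenerate inputs are structured errors: zero-variance scores, Σβ = 0 in
  the GRS rescaling, constant inverse-normal input, single-class outcomes,
  empty strata, < 2 (IVW) or < 3 (Egger/median) pairs, irreconcilable
  alleles.
* BMI values outside (10, 80) kg/m² are rejected as probable unit errors;
  the normal/obese categorization is 18.5–24.9 vs > 30, everything else
  (including underweight) excluded.
* The worked-examples table recomputes published statistics from printed
  inputs. One row (the genetic sex contrast, printed p = 0.18) is carried
  as informational only: the value is not recoverable from the 2-dp rounded
  ORs it would have to be reconstructed from (recomputation gives ≈ 0.23).
  The analogous subset contrast (printed 0.17) *is* recovered within ±0.015.

## Problem sizes in the test and analysis suites

The analysis drivers use n = 50 000; the calibration check uses
n = 100 000; Monte-Carlo recovery and robustness suites use 200 replicates
at n = 20 000 with 73 variants (Egger intercept calibration uses 1000
replicates of the direct summary-statistic generator, which draws harmonized
(bx, by) pairs without an individual-level detour). These sizes resolve all
the tested contrasts with comfortable margins while keeping the default
suite fast; the oracle estimand uses a single 2×10⁶ cohort.

## What the synthetic results do and do not show

The generator reproduces the *statistical* structure of a biobank MR:
instrument strength, confounding, non-collapsibility, pleiotropy,
sex-modified effects, stratification-driven negative-control failure.
It deliberately omits linkage disequilibrium between instruments,
imputation-dosage uncertainty, relatedness/kinship, secondary signals,
assortative mating and real phenotype-curation artefacts. Passing recovery
tests therefore show that the estimators are implemented correctly and
behave as theory predicts under the stated assumptions — not that those
assumptions hold in any particular real cohort. Conversely, the published
headline estimates cannot be recomputed without the original
individual-level data; what is checked against publication is the set of
statistics that are pure functions of printed inputs.
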