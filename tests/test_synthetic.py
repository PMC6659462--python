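"""Generator behaviour: Hardy-Weinberg moments, calibration, outcome model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrkit.synthetic import (CohortTable, ConfigError, SimulationConfig,
                             calibrate_effects, cohort_to_summary_stats,
                             read_cohort, simulate_cohort, simulate_genotypes,
                             write_cohort)


class TestGenotypes:
    def test_hwe_mean_at_half_frequency(self):
        cfg = SimulationConfig(n_samples=100_000, n_variants=2,
                               maf_range=(0.5, 0.5), seed=1)
        g, f = simulate_genotypes(cfg)
        assert np.allclose(f, 0.5)
        assert np.all(np.abs(g.mean(axis=0) - 1.0) < 0.01)

    def test_hwe_variance_at_low_frequency(self):
        cfg = SimulationConfig(n_samples=100_000, n_variants=2,
                               maf_range=(0.05, 0.05), seed=2)
        g, _ = simulate_genotypes(cfg)
        expected = 2 * 0.05 * 0.95
        assert np.all(np.abs(g.var(axis=0) / expected - 1) < 0.05)

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(n_samples=500, n_variants=10, seed=3)
        g1, f1 = simulate_genotypes(cfg)
        g2, f2 = simulate_genotypes(cfg)
        assert np.array_equal(g1, g2) and np.array_equal(f1, f2)

    def test_dosages_in_support(self):
        g, _ = simulate_genotypes(SimulationConfig(n_samples=200, n_variants=5, seed=4))
        assert set(np.unique(g)) <= {0, 1, 2}


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_samples": 0},
        {"n_variants": -1},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"target_r2": 1.0},
        {"pleiotropy_fraction": 1.5},
        {"pleiotropy_mode": "sideways"},
        {"case_fraction": 0.0},
        {"causal_effect": float("nan")},
        {"target_r2": 0.5, "confounder_effect_x": 0.8},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw)


class TestCalibration:
    def test_zero_r2_gives_zero_effects(self):
        tp = calibrate_effects(SimulationConfig(target_r2=0.0, seed=5))
        assert np.all(tp.alpha == 0)

    def test_theoretical_r2_exact(self):
        tp = calibrate_effects(SimulationConfig(n_variants=73, target_r2=0.017, seed=5))
        assert tp.genetic_variance == pytest.approx(0.017, abs=1e-9)

    def test_no_pleiotropy_zero_delta(self):
        tp = calibrate_effects(SimulationConfig(pleiotropy_fraction=0.0, seed=5))
        assert np.all(tp.delta == 0)

    def test_directional_pleiotropy_common_sign(self):
        tp = calibrate_effects(SimulationConfig(
            pleiotropy_fraction=0.4, pleiotropy_mode="directional",
            pleiotropy_scale=0.05, seed=6))
        nz = tp.delta[tp.delta != 0]
        assert len(nz) == round(0.4 * 73)
        assert np.all(nz > 0)

    def test_balanced_pleiotropy_mixed_signs(self):
        tp = calibrate_effects(SimulationConfig(
            n_variants=100, pleiotropy_fraction=1.0, pleiotropy_mode="balanced",
            pleiotropy_scale=0.05, seed=6))
        assert (tp.delta > 0).any() and (tp.delta < 0).any()


class TestCohort:
    def test_prevalence_matches_case_fraction(self, cohort100k):
        cfg, cohort, _ = cohort100k
        assert abs(cohort.outcome.mean() - cfg.case_fraction) < 0.005

    def test_target_prevalence_014(self):
        cfg = SimulationConfig(n_samples=100_000, case_fraction=0.14, seed=21)
        cohort, _ = simulate_cohort(cfg)
        assert 0.135 <= cohort.outcome.mean() <= 0.145

    def test_null_model_grs_quartile_odds_ratio_covers_one(self):
        cfg = SimulationConfig(n_samples=50_000, causal_effect=0.0,
                               pleiotropy_fraction=0.0, seed=22)
        cohort, tp = simulate_cohort(cfg)
        grs = cohort.dosages.astype(float) @ tp.alpha
        top = grs >= np.quantile(grs, 0.75)
        bottom = grs <= np.quantile(grs, 0.25)
        y_top, y_bot = cohort.outcome[top], cohort.outcome[bottom]
        table = np.array([[y_top.sum(), (1 - y_top).sum()],
                          [y_bot.sum(), (1 - y_bot).sum()]], dtype=float)
        log_or = np.log(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
        se = np.sqrt((1 / table).sum())
        assert abs(log_or) < 1.96 * se

    def test_score_independent_of_confounder_without_stratification(self, cohort100k):
        cfg, cohort, tp = cohort100k
        grs = cohort.dosages.astype(float) @ tp.alpha
        u = cohort.covariates["confounder_proxy"].to_numpy()
        r = np.corrcoef(grs, u)[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_samples)

    def test_controls_do_not_load_on_exposure_residual(self):
        # partial association of the control with X given (sep, U-proxy) is null
        cfg = SimulationConfig(n_samples=50_000, stratification_effect=0.3, seed=23)
        cohort, _ = simulate_cohort(cfg)
        design = sm.add_constant(np.column_stack([
            cohort.exposure,
            cohort.covariates["sep"].to_numpy(),
            cohort.covariates["confounder_proxy"].to_numpy()]))
        fit = sm.OLS(cohort.controls["control_cont"].to_numpy(), design).fit()
        assert abs(fit.params[1]) < 3 * fit.bse[1]

    def test_roundtrip_write_read(self, tmp_path):
        cfg = SimulationConfig(n_samples=300, n_variants=8, seed=24)
        cohort, _ = simulate_cohort(cfg)
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert np.array_equal(back.dosages, cohort.dosages)
        assert np.allclose(back.exposure, cohort.exposure)
        assert np.array_equal(back.outcome, cohort.outcome)


class TestSummaryScan:
    def test_null_scan_p_calibration(self):
        # no genetic effects: ~5% of variants reach p<0.05
        cfg = SimulationConfig(n_samples=20_000, n_variants=400, target_r2=0.0,
                               causal_effect=0.0, seed=31)
        cohort, _ = simulate_cohort(cfg)
        stats_tab = cohort_to_summary_stats(cohort, "exposure")
        frac = (stats_tab["pval"] < 0.05).mean()
        # binomial 99% bounds around 0.05 at k=400
        bound = 2.58 * np.sqrt(0.05 * 0.95 / 400)
        assert abs(frac - 0.05) <= bound

    def test_scan_beta_consistent_with_alpha(self, cohort100k):
        _, cohort, tp = cohort100k
        stats_tab = cohort_to_summary_stats(cohort, "exposure")
        z = (stats_tab["beta"].to_numpy() - tp.alpha) / stats_tab["se"].to_numpy()
        assert np.mean(np.abs(z) < 3) > 0.98

    def test_scan_deterministic(self):
        cfg = SimulationConfig(n_samples=2_000, n_variants=10, seed=32)
        t1 = cohort_to_summary_stats(simulate_cohort(cfg)[0], "outcome")
        t2 = cohort_to_summary_stats(simulate_cohort(cfg)[0], "outcome")
        pd.testing.assert_frame_equal(t1, t2)

    def test_logistic_scan_matches_statsmodels(self):
        cfg = SimulationConfig(n_samples=4_000, n_variants=5, seed=33)
        cohort, _ = simulate_cohort(cfg)
        tab = cohort_to_summary_stats(cohort, "outcome")
        j = 2
        X = sm.add_constant(cohort.dosages[:, j].astype(float))
        fit = sm.Logit(cohort.outcome.astype(float), X).fit(disp=0)
        assert tab["beta"][j] == pytest.approx(fit.params[1], abs=1e-6)
        assert tab["se"][j] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_monomorphic_variant_flagged_not_dropped(self):
        cfg = SimulationConfig(n_samples=1_000, n_variants=6, seed=34)
        cohort, _ = simulate_cohort(cfg)
        cohort.dosages[:, 3] = 1  # force a monomorphic column
        tab = cohort_to_summary_stats(cohort, "exposure")
        assert len(tab) == 6
        assert tab["flag"][3] == "monomorphic"
        assert np.isnan(tab["se"][3])


class TestOracle:
    def test_oracle_close_to_conditional_theta_at_modest_effect(self):
        # non-collapsibility attenuation is small at OR ~ 1.2
        from mrkit.synthetic import oracle_estimand
        cfg = SimulationConfig(n_samples=10_000, seed=41)
        theta_star = oracle_estimand(cfg, n_oracle=400_000)
        assert abs(theta_star - cfg.causal_effect) < 0.06

    def test_oracle_requires_first_stage(self):
        from mrkit.synthetic import oracle_estimand
        with pytest.raises(ConfigError):
            oracle_estimand(SimulationConfig(target_r2=0.0, seed=41))
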