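"""Wald-from-CI, Fisher z, meta-analysis, over-identification, screens, controls."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mrkit.inference import (EstimateWithSE, compare_estimates, estimate_from_ci,
                             fisher_z_diff, meta_fixed, negative_control_battery,
                             overidentification_test, pleiotropy_screen,
                             wald_p_from_ci)
from mrkit.onesample import sex_stratified
from mrkit.synthetic import (SimulationConfig, simulate_cohort,
                             simulate_summary_pairs)
from tests.conftest import make_pairs


class TestWaldFromCI:
    def test_symmetric_ci_about_zero_gives_p_one(self):
        assert wald_p_from_ci(0.0, -0.1, 0.1, scale="linear") == pytest.approx(1.0)

    def test_or_scale_works_on_logs(self):
        p_or = wald_p_from_ci(1.5, 1.1, 2.05, scale="log_odds_from_or")
        p_log = wald_p_from_ci(np.log(1.5), np.log(1.1), np.log(2.05), scale="linear")
        assert p_or == pytest.approx(p_log)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            wald_p_from_ci(1.5, -0.1, 2.0, scale="log_odds_from_or")

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValueError):
            wald_p_from_ci(0.2, 0.3, 0.3)

    @pytest.mark.parametrize("beta,se", [(0.166, 0.0416), (-0.5, 0.2), (0.01, 0.005)])
    def test_roundtrip_matches_direct_wald(self, beta, se):
        p_ci = wald_p_from_ci(beta, beta - 1.96 * se, beta + 1.96 * se)
        p_direct = 2 * stats.norm.sf(abs(beta) / se)
        assert p_ci == pytest.approx(p_direct, abs=1e-12)


class TestFisherZ:
    def test_normal_cdf_oracle(self):
        z, p = fisher_z_diff(EstimateWithSE(1.0, 1.0), EstimateWithSE(0.0, 1.0))
        assert z == pytest.approx(0.7071, abs=1e-4)
        assert p == pytest.approx(0.4795, abs=1e-4)

    def test_identical_estimates(self):
        a = EstimateWithSE(0.3, 0.1)
        z, p = fisher_z_diff(a, a)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetric_in_arguments(self):
        a, b = EstimateWithSE(0.4, 0.15), EstimateWithSE(0.1, 0.2)
        z_ab, p_ab = fisher_z_diff(a, b)
        z_ba, p_ba = fisher_z_diff(b, a)
        assert z_ab == -z_ba and p_ab == p_ba

    def test_null_p_uniform_across_sex_strata(self):
        # theta=0, no pleiotropy, modifier 1: the sex-contrast p is U(0,1)
        base = SimulationConfig(n_samples=4_000, n_variants=20,
                                causal_effect=0.0, seed=0)
        pvals = []
        for rep in range(150):
            cfg = dataclasses.replace(base, seed=60_000 + rep)
            cohort, tp = simulate_cohort(cfg)
            score = cohort.dosages.astype(float) @ tp.alpha
            res = sex_stratified(cohort.outcome, cohort.exposure, score, cohort.sex)
            comp = compare_estimates(res[1], res[0])
            pvals.append(comp.p_difference)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMetaFixed:
    def test_two_identical_estimates(self):
        est, het = meta_fixed([EstimateWithSE(0.2, 0.1), EstimateWithSE(0.2, 0.1)])
        assert est.estimate == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))
        assert het.q == pytest.approx(0.0, abs=1e-20)

    def test_hand_inverse_variance_oracle(self):
        est, het = meta_fixed([EstimateWithSE(0.1, 0.1), EstimateWithSE(0.3, 0.2)])
        assert est.estimate == pytest.approx(0.14)
        assert est.se == pytest.approx(0.0894, abs=5e-4)
        assert het.q == pytest.approx(0.8)
        assert het.p_q == pytest.approx(0.371, abs=5e-4)

    def test_single_estimate_returned_unchanged(self):
        est, het = meta_fixed([EstimateWithSE(0.25, 0.07)])
        assert est.estimate == pytest.approx(0.25)
        assert est.se == pytest.approx(0.07)
        assert het.df == 0 and het.p_q == 1.0

    def test_k_copies_shrink_se_by_sqrt_k(self):
        for k in (2, 5, 9):
            est, _ = meta_fixed([EstimateWithSE(0.2, 0.12)] * k)
            assert est.se == pytest.approx(0.12 / np.sqrt(k), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([])


class TestOveridentification:
    def test_identical_subset_estimates_give_p_one(self):
        a = EstimateWithSE(0.2, 0.1)
        comp = compare_estimates(a, EstimateWithSE(0.2, 0.1))
        assert comp.p_difference == pytest.approx(1.0)

    def test_overlapping_subsets_rejected(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], 0.01)
        with pytest.raises(ValueError, match="overlap"):
            overidentification_test(pairs, pairs.iloc[1:])

    def test_directional_pleiotropy_in_one_subset_detected(self):
        clean = simulate_summary_pairs(n_variants=30, theta=0.2, seed=61)
        dirty = simulate_summary_pairs(n_variants=30, theta=0.2,
                                       pleiotropy_fraction=1.0,
                                       pleiotropy_mode="directional",
                                       pleiotropy_scale=0.06, seed=62)
        dirty["snp"] = ["rsB" + s for s in dirty["snp"]]
        comp = overidentification_test(clean, dirty)
        assert comp.p_difference < 0.05


class TestPleiotropyScreen:
    def test_zero_outcome_effect_not_flagged(self):
        pairs = make_pairs([0.05], [0.0], 0.01)
        assert not pleiotropy_screen(pairs, 0.125)["flagged"][0]

    def test_hand_conversion_flags_large_outcome_effect(self):
        pairs = make_pairs([0.05], [0.3], 0.01)
        out = pleiotropy_screen(pairs, 0.125)
        assert out["by_sd"][0] == pytest.approx(0.3 * np.sqrt(0.125 * 0.875), abs=1e-6)
        assert out["by_sd"][0] == pytest.approx(0.0992, abs=5e-4)
        assert bool(out["flagged"][0])

    def test_larger_exposure_effect_not_flagged(self):
        pairs = make_pairs([0.15], [0.3], 0.01)
        assert not pleiotropy_screen(pairs, 0.125)["flagged"][0]

    def test_invalid_case_fraction(self):
        with pytest.raises(ValueError):
            pleiotropy_screen(make_pairs([0.1], [0.1], 0.01), 1.5)


@pytest.fixture(scope="module")
def valid_instrument_run():
    cfg = SimulationConfig(n_samples=50_000, stratification_effect=0.0, seed=63)
    cohort, tp = simulate_cohort(cfg)
    score = cohort.dosages.astype(float) @ tp.alpha
    controls = cohort.controls.assign(
        pure_noise=np.random.default_rng(63).normal(size=cfg.n_samples))
    return negative_control_battery(controls, cohort.exposure, score,
                                    cohort.covariates["sep"].to_numpy())


class TestNegativeControls:
    def test_confounder_driven_controls_have_null_iv(self, valid_instrument_run):
        iv = valid_instrument_run.query("estimator == 'iv' and not adjusted")
        for _, row in iv.iterrows():
            assert row["ci_low"] <= 0 <= row["ci_high"], row["control"]

    def test_pure_noise_control_all_four_null(self, valid_instrument_run):
        sub = valid_instrument_run.query("control == 'pure_noise'")
        assert len(sub) == 4
        assert ((sub["ci_low"] <= 0) & (sub["ci_high"] >= 0)).all()

    def test_observational_association_present_for_confounded_controls(self, valid_instrument_run):
        obs = valid_instrument_run.query(
            "estimator == 'observational' and not adjusted and control != 'pure_noise'")
        assert (obs["p"] < 1e-6).all()
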