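"""Summary-statistic estimators: Wald ratio, IVW, Egger, weighted median."""

import numpy as np
import pytest

from mrkit.twosample import egger, ivw, wald_ratio, weighted_median
from tests.conftest import make_pairs


class TestWaldRatio:
    def test_formula(self):
        est = wald_ratio({"bx": 0.1, "by": 0.05, "se_y": 0.01})
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_numerator(self):
        assert wald_ratio({"bx": 0.1, "by": 0.0, "se_y": 0.01}).estimate == 0.0

    def test_orientation_invariance(self):
        a = wald_ratio({"bx": 0.1, "by": 0.05, "se_y": 0.01})
        b = wald_ratio({"bx": -0.1, "by": -0.05, "se_y": 0.01})
        assert a.estimate == b.estimate and a.se == b.se

    def test_zero_bx_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio({"bx": 0.0, "by": 0.05, "se_y": 0.01})


class TestIVW:
    def test_exact_proportionality(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], 0.01)
        est, het = ivw(pairs, "fixed")
        assert est.estimate == pytest.approx(0.5)
        assert het.q == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_two_variant_example(self):
        pairs = make_pairs([0.1, 0.2], [0.08, 0.12], [0.05, 0.04])
        est, het = ivw(pairs, "fixed")
        assert est.estimate == pytest.approx(18.2 / 29, abs=1e-10)
        assert est.se == pytest.approx(1 / np.sqrt(29), abs=1e-10)
        assert het.q == pytest.approx(0.1379, abs=5e-4)

    def test_negating_outcomes_negates_estimate(self):
        rng = np.random.default_rng(1)
        pairs = make_pairs(rng.uniform(0.01, 0.05, 10),
                           rng.normal(0, 0.02, 10), rng.uniform(0.01, 0.03, 10))
        est, _ = ivw(pairs, "fixed")
        neg = pairs.assign(by=-pairs["by"])
        est_n, _ = ivw(neg, "fixed")
        assert est_n.estimate == pytest.approx(-est.estimate)
        assert est_n.se == pytest.approx(est.se)

    def test_matches_independent_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = rng.integers(2, 30)
            bx = rng.normal(0.03, 0.02, k)
            bx[bx == 0] = 0.01
            by = rng.normal(0, 0.05, k)
            se_y = rng.uniform(0.005, 0.05, k)
            pairs = make_pairs(bx, by, se_y)
            est, _ = ivw(pairs, "fixed")
            # independent route: weighted least squares through the origin by
            # QR on the rescaled design
            beta_oracle = np.linalg.lstsq((bx / se_y)[:, None], by / se_y, rcond=None)[0][0]
            assert est.estimate == pytest.approx(beta_oracle, abs=1e-10)

    def test_random_effects_inflates_se_under_heterogeneity(self):
        pairs = make_pairs([0.02, 0.03, 0.04, 0.05], [0.10, -0.08, 0.12, -0.11], 0.01)
        fixed, het = ivw(pairs, "fixed")
        random_, _ = ivw(pairs, "random")
        assert het.q > het.df
        assert random_.se == pytest.approx(fixed.se * np.sqrt(het.q / het.df))

    def test_single_pair_directed_to_wald_ratio(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(make_pairs([0.1], [0.05], 0.01))

    def test_i2_definition(self):
        pairs = make_pairs([0.02, 0.03, 0.04, 0.05], [0.10, -0.08, 0.12, -0.11], 0.01)
        _, het = ivw(pairs)
        assert het.i2 == pytest.approx(max(0.0, (het.q - het.df) / het.q))
        assert 0 <= het.i2 < 1


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = make_pairs(bx, 0.1 + 0.5 * bx, 0.01)
        slope, intercept = egger(pairs)
        assert slope.estimate == pytest.approx(0.5, abs=1e-10)
        assert intercept.estimate == pytest.approx(0.1, abs=1e-10)

    def test_unweighted_least_squares_oracle(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.12, 0.24, 0.30], 0.01)
        slope, intercept = egger(pairs)
        # independent oracle: equal weights -> ordinary polyfit
        b1, b0 = np.polyfit([0.1, 0.2, 0.3], [0.12, 0.24, 0.30], 1)
        assert slope.estimate == pytest.approx(b1, abs=1e-10)  # 0.9
        assert intercept.estimate == pytest.approx(b0, abs=1e-10)  # 0.04

    def test_nesting_through_origin(self):
        bx = np.array([0.1, 0.2, 0.4])
        pairs = make_pairs(bx, 0.5 * bx, 0.01)
        slope, intercept = egger(pairs)
        est_ivw, _ = ivw(pairs, "fixed")
        assert intercept.estimate == pytest.approx(0.0, abs=1e-12)
        assert slope.estimate == pytest.approx(est_ivw.estimate, abs=1e-12)

    def test_orientation_rule_makes_fit_sign_stable(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.01, 0.05, 8)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.005, 8)
        pairs = make_pairs(bx, by, 0.01)
        flip = pairs.copy()
        flip.loc[:2, "bx"] *= -1
        flip.loc[:2, "by"] *= -1
        s1, i1 = egger(pairs)
        s2, i2 = egger(flip)
        assert s1.estimate == pytest.approx(s2.estimate)
        assert i1.estimate == pytest.approx(i2.estimate)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">=3"):
            egger(make_pairs([0.1, 0.2], [0.05, 0.1], 0.01))

    def test_rank_deficient_design(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            egger(make_pairs([0.2, 0.2, 0.2], [0.05, 0.06, 0.07], 0.01))


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.02, 0.05, 0.09], 0.01)
        est = weighted_median(pairs, bootstrap_reps=50, seed=0)
        assert est.estimate == pytest.approx(0.5)

    def test_hand_interpolation_oracle(self):
        # ratios (0.1, 0.4, 0.6), weights (1, 1, 2):
        # positions (0.125, 0.375, 0.75) -> 0.4 + 0.2 * 0.125/0.375
        se_y = np.array([0.1, 0.1, 0.1])
        bx = np.array([0.1, 0.1, 0.1 * np.sqrt(2)])
        by = np.array([0.1, 0.4, 0.6]) * bx
        pairs = make_pairs(bx, by, se_y)
        est = weighted_median(pairs, bootstrap_reps=50, seed=0)
        assert est.estimate == pytest.approx(0.4 + 0.2 * (0.125 / 0.375), abs=1e-12)

    def test_identical_ratios_recovered_with_small_se(self):
        bx = np.array([0.1, 0.2, 0.3])
        pairs = make_pairs(bx, 0.7 * bx, 1e-5, se_x=1e-7)
        est = weighted_median(pairs, bootstrap_reps=100, seed=1)
        assert est.estimate == pytest.approx(0.7, abs=1e-6)
        assert est.se < 1e-3

    def test_joint_sign_flip_invariance(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.01, 0.05, 9)
        by = 0.3 * bx + rng.normal(0, 0.01, 9)
        pairs = make_pairs(bx, by, 0.02)
        flip = pairs.copy()
        flip.loc[:3, ["bx", "by"]] *= -1
        e1 = weighted_median(pairs, bootstrap_reps=50, seed=2)
        e2 = weighted_median(flip, bootstrap_reps=50, seed=2)
        assert e1.estimate == pytest.approx(e2.estimate)

    def test_penalization_downweights_gross_outlier(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.02, 0.05, 12)
        by = 0.4 * bx + rng.normal(0, 0.002, 12)
        by[0] = 0.4 * bx[0] + 0.25  # one wildly pleiotropic variant
        pairs = make_pairs(bx, by, 0.005)
        plain = weighted_median(pairs, penalized=False, bootstrap_reps=50, seed=3)
        pen = weighted_median(pairs, penalized=True, bootstrap_reps=50, seed=3)
        assert abs(pen.estimate - 0.4) <= abs(plain.estimate - 0.4) + 1e-9

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">=3"):
            weighted_median(make_pairs([0.1, 0.2], [0.05, 0.1], 0.01))
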