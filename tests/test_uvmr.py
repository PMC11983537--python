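"""Univariable estimators against brute-force oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_harmonized
from oracles import egger_oracle, ivw_oracle, weighted_median_oracle
from mrmediation import (
    CollinearityError,
    DegenerateInputError,
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    ratio_estimates,
    to_odds_ratio,
    weighted_median,
)


class TestRatioEstimates:
    def test_direct_division(self):
        h = make_harmonized([0.1], [0.02], sey=[0.1])
        tab = ratio_estimates(h)
        assert tab.loc[0, "ratio"] == pytest.approx(0.2)
        assert tab.loc[0, "se"] == pytest.approx(1.0)

    def test_null_outcome_vector(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])
        assert (ratio_estimates(h)["ratio"] == 0).all()

    def test_three_snp_hand_arithmetic(self):
        h = make_harmonized([0.1, -0.2, 0.4], [0.05, 0.1, -0.2], sey=[0.1, 0.2, 0.4])
        tab = ratio_estimates(h)
        np.testing.assert_allclose(tab["ratio"], [0.5, -0.5, -0.5])
        np.testing.assert_allclose(tab["se"], [1.0, 1.0, 1.0])

    def test_zero_exposure_effect_names_variant(self):
        h = make_harmonized([0.1, 0.0], [0.1, 0.1], ids=["rsA", "rsB"])
        with pytest.raises(DegenerateInputError, match="rsB"):
            ratio_estimates(h)


class TestIvw:
    def test_identical_variants_give_common_ratio(self):
        h = make_harmonized([0.1, 0.1], [0.03, 0.03], sey=[0.05, 0.05])
        est = ivw(h)
        assert est.b == pytest.approx(0.3)
        assert est.q == pytest.approx(0.0)

    def test_single_variant_is_wald_ratio(self):
        h = make_harmonized([0.1], [0.02], sey=[0.1])
        with pytest.warns(UserWarning, match="single instrument"):
            est = ivw(h)
        assert est.b == pytest.approx(0.2)
        assert est.se == pytest.approx(1.0)

    def test_matches_through_origin_oracle(self, five_snp_set):
        est = ivw(five_snp_set, mode="fixed")
        b, se = ivw_oracle(
            five_snp_set.exposure_beta,
            five_snp_set.outcome_beta,
            five_snp_set.outcome_se,
        )
        assert est.b == pytest.approx(b, rel=1e-12)
        assert est.se == pytest.approx(se, rel=1e-12)

    def test_random_effects_se_floor(self, five_snp_set):
        fixed = ivw(five_snp_set, mode="fixed")
        random = ivw(five_snp_set, mode="random")
        assert random.se >= fixed.se
        assert random.b == pytest.approx(fixed.b)

    def test_auto_switches_on_heterogeneity(self):
        bx = np.full(6, 0.1)
        by = np.array([0.01, 0.012, 0.009, 0.011, 0.01, 0.08])  # one discordant
        h = make_harmonized(bx, by, sey=np.full(6, 0.005))
        est = ivw(h, mode="auto")
        assert est.q_p < 0.05
        assert est.method == "IVW-random"

    def test_or_fields_consistent(self, five_snp_set):
        est = ivw(five_snp_set)
        assert est.or_value == pytest.approx(np.exp(est.b))
        assert est.or_low < est.or_value < est.or_high


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.01 + 0.3 * bx
        h = make_harmonized(bx, by, sey=np.full(4, 0.02))
        est = egger(h)
        assert est.b == pytest.approx(0.3, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_null_intercept_statistic(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonized(bx, 0.3 * bx, sey=np.full(4, 0.02))
        est = egger(h)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert est.egger_intercept_p == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        bx = rng.normal(0.1, 0.05, 6)
        sey = rng.uniform(0.01, 0.05, 6)
        by = 0.02 + 0.4 * bx + rng.normal(0, 1, 6) * sey
        h = make_harmonized(bx, by, sey=sey)
        est = egger(h)
        intercept, slope, se_int, se_slope = egger_oracle(bx, by, sey)
        assert est.b == pytest.approx(slope, rel=1e-10)
        assert est.se == pytest.approx(se_slope, rel=1e-10)
        assert est.egger_intercept == pytest.approx(intercept, rel=1e-10)

    def test_collinear_exposure_errors(self):
        h = make_harmonized([0.1, 0.1, -0.1], [0.02, 0.01, 0.03])
        with pytest.raises(CollinearityError):
            egger(h)

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.02, 0.03])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], sey=np.full(3, 0.05))
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.b == pytest.approx(2.0)

    def test_dominant_weight_limit(self):
        # first variant carries ~10^4 times the weight of the others
        h = make_harmonized(
            [0.5, 0.005, 0.005], [0.5, 0.015, 0.02], sey=np.full(3, 0.05)
        )
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.b == pytest.approx(1.0, abs=0.01)

    def test_matches_interpolation_oracle(self, five_snp_set):
        est = weighted_median(five_snp_set, n_boot=50, seed=0)
        r = five_snp_set.outcome_beta / five_snp_set.exposure_beta
        w = (five_snp_set.exposure_beta / five_snp_set.outcome_se) ** 2
        assert est.b == pytest.approx(weighted_median_oracle(r, w), rel=1e-12)

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.02, 0.03])
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h, n_boot=50, seed=0)

    def test_bootstrap_se_reproducible(self, five_snp_set):
        a = weighted_median(five_snp_set, n_boot=200, seed=42)
        b = weighted_median(five_snp_set, n_boot=200, seed=42)
        assert a.se == b.se

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_estimate_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        bx = rng.normal(0.1, 0.05, n)
        bx[np.abs(bx) < 1e-3] = 0.05
        by = rng.normal(0, 0.05, n)
        h = make_harmonized(bx, by, sey=rng.uniform(0.01, 0.05, n))
        r = by / bx
        est = weighted_median(h, n_boot=10, seed=0)
        assert r.min() - 1e-12 <= est.b <= r.max() + 1e-12


class TestCochranQ:
    def test_homogeneous_ratios(self):
        h = make_harmonized([0.1, 0.2], [0.03, 0.06], sey=[0.05, 0.05])
        q, p = cochran_q(h)
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_snp_hand_arithmetic(self):
        # ratios 0.5 and 1.0, weights 4 and 4 -> b = 0.75, Q = 4*(0.25^2)*2 = 0.5
        h = make_harmonized([0.1, 0.1], [0.05, 0.1], sey=[0.05, 0.05])
        q, _ = cochran_q(h)
        assert q == pytest.approx(0.5)

    def test_weight_scaling_law(self, five_snp_set):
        q1, _ = cochran_q(five_snp_set)
        scaled = make_harmonized(
            five_snp_set.exposure_beta,
            five_snp_set.outcome_beta,
            sey=10 * five_snp_set.outcome_se,
        )
        q2, _ = cochran_q(scaled)
        assert q2 == pytest.approx(q1 / 100)

    def test_single_variant_undefined(self):
        h = make_harmonized([0.1], [0.02])
        with pytest.raises(DegenerateInputError):
            cochran_q(h)


class TestLeaveOneOut:
    def test_row_count(self, five_snp_set):
        tab = leave_one_out(five_snp_set)
        assert len(tab) == five_snp_set.nsnp + 1
        assert tab["omitted"].iloc[-1] == "(none)"

    def test_homogeneous_rows_near_full(self):
        bx = np.full(5, 0.1)
        h = make_harmonized(bx, 0.3 * bx, sey=np.full(5, 0.01))
        tab = leave_one_out(h)
        np.testing.assert_allclose(tab["b"], 0.3, atol=1e-12)

    def test_outlier_departs_most(self):
        bx = np.full(6, 0.1)
        by = np.array([0.03, 0.031, 0.029, 0.03, 0.03, 0.3])  # 10x ratio outlier
        h = make_harmonized(bx, by, sey=np.full(6, 0.01))
        tab = leave_one_out(h)
        full_b = tab["b"].iloc[-1]
        departures = (tab["b"].iloc[:-1] - full_b).abs()
        assert departures.idxmax() == 5


class TestOddsRatio:
    @pytest.mark.parametrize(
        "b, expected",
        [(0.0, 1.0), (0.127, 1.135), (0.155, 1.168), (0.506, 1.659)],
    )
    def test_reported_conversions(self, b, expected):
        or_value, _, _ = to_odds_ratio(b, 0.1)
        assert round(or_value, 3) == pytest.approx(expected)

    def test_ci_ordering(self):
        or_value, lo, hi = to_odds_ratio(0.2, 0.1)
        assert lo < or_value < hi


class TestEstimatorInvariances:
    def test_single_variant_sign_flip(self, five_snp_set):
        """Simultaneous sign flip of one (betaX, betaY) pair changes nothing."""
        flipped = make_harmonized(
            five_snp_set.exposure_beta * np.array([1, 1, -1, 1, 1]),
            five_snp_set.outcome_beta * np.array([1, 1, -1, 1, 1]),
            sex=five_snp_set.exposure_se,
            sey=five_snp_set.outcome_se,
        )
        assert ivw(five_snp_set, "fixed").b == pytest.approx(ivw(flipped, "fixed").b)
        assert egger(five_snp_set).b == pytest.approx(egger(flipped).b)
        assert egger(five_snp_set).egger_intercept == pytest.approx(
            egger(flipped).egger_intercept
        )
        assert weighted_median(five_snp_set, 10, seed=0).b == pytest.approx(
            weighted_median(flipped, 10, seed=0).b
        )

    def test_row_permutation(self, five_snp_set):
        perm = np.array([3, 0, 4, 1, 2])
        shuffled = make_harmonized(
            five_snp_set.exposure_beta[perm],
            five_snp_set.outcome_beta[perm],
            sex=five_snp_set.exposure_se[perm],
            sey=five_snp_set.outcome_se[perm],
        )
        assert ivw(five_snp_set, "fixed").b == pytest.approx(ivw(shuffled, "fixed").b)
        assert egger(five_snp_set).b == pytest.approx(egger(shuffled).b)
        assert weighted_median(five_snp_set, 10, seed=0).b == pytest.approx(
            weighted_median(shuffled, 10, seed=0).b
        )
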