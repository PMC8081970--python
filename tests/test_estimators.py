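"""Wald ratio, IVW pooling, Cochran's Q, OR/CI, Bonferroni.

Expected numbers are frozen from independent hand arithmetic on the
two-decimal instrument table (documented per test), and the IVW estimator
is cross-checked against an origin-constrained weighted least-squares fit
(statsmodels) on random instances.
"""

import math

import numpy as np
import pytest

from mrtools import (
    EstimationError,
    HarmonizedPair,
    WaldEstimate,
    bonferroni_flag,
    cochran_q,
    ivw_fixed,
    ivw_scaled,
    or_ci,
    wald_ratio,
)


def pair(vid="rs1", x=0.5, sigma_x=0.05, y=0.1, sigma_y=0.02):
    return HarmonizedPair(
        variant_id=vid, x=x, sigma_x=sigma_x, y=y, sigma_y=sigma_y,
        effect_allele="A", palindromic=False, action="unchanged",
    )


# Wald estimates from the IL-1Ra rows: ratio = y/x, se = sigma_y/|x|
#   rs1542176: -0.01/0.33 = -0.0303030, se 0.02/0.33 = 0.0606061
#   rs6743376: -0.04/0.46 = -0.0869565, se 0.02/0.46 = 0.0434783
IL1RA_ESTIMATES = [
    WaldEstimate("rs1542176", -0.01 / 0.33, 0.02 / 0.33),
    WaldEstimate("rs6743376", -0.04 / 0.46, 0.02 / 0.46),
]


class TestWaldRatio:
    def test_sil2ra_hand_arithmetic(self):
        # 0.12/0.63 = 0.190476, se 0.03/0.63 = 0.047619, exp -> 1.2098
        est = wald_ratio(pair(x=0.63, sigma_x=0.05, y=0.12, sigma_y=0.03))
        assert est.ratio == pytest.approx(0.19048, abs=1e-5)
        assert est.se == pytest.approx(0.04762, abs=1e-5)
        assert math.exp(est.ratio) == pytest.approx(1.21, abs=0.005)

    def test_zero_outcome_effect(self):
        est = wald_ratio(pair(x=0.5, y=0.0, sigma_y=0.02))
        assert est.ratio == 0.0
        assert est.se == pytest.approx(0.04)

    def test_allele_flip_invariance(self):
        a = wald_ratio(pair(x=0.5, y=0.1, sigma_y=0.02))
        b = wald_ratio(pair(x=-0.5, y=-0.1, sigma_y=0.02))
        assert a.ratio == pytest.approx(b.ratio) and a.se == pytest.approx(b.se)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(EstimationError):
            wald_ratio(pair(x=0.0))


class TestIVWFixed:
    def test_il1ra_weighted_sum_arithmetic(self):
        # weights X^2/sigma_Y^2: 272.25 and 529; numerator -8.25 - 46.0
        # beta = -54.25/801.25 = -0.067707, se = 1/sqrt(801.25) = 0.035327
        res = ivw_fixed(IL1RA_ESTIMATES, exposure_id="IL-1Ra")
        assert res.beta == pytest.approx(-0.06771, abs=1e-5)
        assert res.se == pytest.approx(0.03533, abs=1e-5)
        assert res.or_point == pytest.approx(0.9345, abs=1e-3)
        assert res.n_snp == 2 and res.q_df == 1

    def test_single_estimate_reduces_to_wald(self):
        est = wald_ratio(pair(x=0.63, y=0.12, sigma_y=0.03))
        res = ivw_fixed([est])
        assert res.beta == pytest.approx(est.ratio, rel=1e-14)
        assert res.se == pytest.approx(est.se, rel=1e-14)
        assert res.q is None and res.q_df is None

    def test_duplicated_estimate_shrinks_se_by_sqrt2(self):
        est = wald_ratio(pair())
        one = ivw_fixed([est])
        two = ivw_fixed([est, est])
        assert two.beta == pytest.approx(one.beta, rel=1e-14)
        assert two.se == pytest.approx(one.se / math.sqrt(2), rel=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(EstimationError):
            ivw_fixed([])

    def test_pooled_beta_within_ratio_range(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(2, 8)
            ests = [
                WaldEstimate(f"rs{i}", float(rng.normal(0, 0.3)), float(rng.uniform(0.01, 0.5)))
                for i in range(n)
            ]
            beta = ivw_fixed(ests).beta
            ratios = [e.ratio for e in ests]
            assert min(ratios) - 1e-12 <= beta <= max(ratios) + 1e-12

    def test_matches_origin_wls_oracle(self):
        """IVW coefficient equals weighted least squares of Y on X through the origin."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            x = rng.uniform(0.1, 0.8, n) * rng.choice([-1, 1], n)
            sigma_y = rng.uniform(0.01, 0.1, n)
            y = 0.2 * x + rng.normal(0, sigma_y)
            pairs = [pair(vid=f"rs{i}", x=x[i], y=y[i], sigma_y=sigma_y[i]) for i in range(n)]
            res = ivw_fixed([wald_ratio(p) for p in pairs])
            fit = sm.WLS(y, x[:, None], weights=1 / sigma_y**2).fit()
            assert res.beta == pytest.approx(fit.params[0], rel=1e-10)


class TestCochranQ:
    def test_il1ra_hand_arithmetic(self):
        # q = 272.25*(-0.030303+0.067707)^2 + 529*(-0.086957+0.067707)^2 = 0.5769
        beta = ivw_fixed(IL1RA_ESTIMATES).beta
        q, q_df, q_p = cochran_q(IL1RA_ESTIMATES, beta)
        assert q == pytest.approx(0.5769, abs=1e-3)
        assert q_df == 1
        assert q_p == pytest.approx(0.4475, abs=1e-3)

    def test_il18_rounded_inputs(self):
        # ratios -0.2 (w 25) and -0.125 (w 16): pooled -7/41, q = 0.0549
        ests = [
            WaldEstimate("rs2250417", -0.02 / 0.10, 0.02 / 0.10),
            WaldEstimate("rs7577696", -0.01 / 0.08, 0.02 / 0.08),
        ]
        beta = ivw_fixed(ests).beta
        assert beta == pytest.approx(-7 / 41, rel=1e-10)
        q, q_df, _ = cochran_q(ests, beta)
        assert q == pytest.approx(0.0549, abs=1e-3)
        assert q_df == 1

    def test_identical_ratios_give_zero_q(self):
        ests = [WaldEstimate("a", 0.1, 0.05), WaldEstimate("b", 0.1, 0.08)]
        q, _, q_p = cochran_q(ests, 0.1)
        assert q == pytest.approx(0.0, abs=1e-14)
        assert q_p == pytest.approx(1.0)

    def test_single_estimate_raises(self):
        with pytest.raises(EstimationError):
            cochran_q([WaldEstimate("a", 0.1, 0.05)], 0.1)


class TestIVWScaled:
    def test_overdispersed_pair_inflates_se(self):
        # ratios +0.1154 (se 0.0769) and -0.1304 (se 0.0870):
        # q = 4.48, inflation = sqrt(4.48) = 2.12, se 0.0576 -> 0.122
        ests = [WaldEstimate("a", 0.1154, 0.0769), WaldEstimate("b", -0.1304, 0.0870)]
        fixed = ivw_fixed(ests)
        scaled = ivw_scaled(ests)
        assert fixed.q == pytest.approx(4.48, abs=0.01)
        assert scaled.se / fixed.se == pytest.approx(math.sqrt(fixed.q), rel=1e-9)
        assert scaled.se == pytest.approx(0.122, abs=1e-3)
        assert scaled.or_point == pytest.approx(1.01, abs=0.005)
        assert scaled.ci_low == pytest.approx(0.79, abs=0.005)
        assert scaled.ci_high == pytest.approx(1.28, abs=0.005)

    def test_underdispersion_floors_at_fixed(self):
        scaled = ivw_scaled(IL1RA_ESTIMATES)
        fixed = ivw_fixed(IL1RA_ESTIMATES)
        assert fixed.q / fixed.q_df < 1
        assert scaled.se == pytest.approx(fixed.se, rel=1e-14)
        assert scaled.beta == pytest.approx(fixed.beta, rel=1e-14)

    def test_identical_ratios_equal_fixed(self):
        ests = [WaldEstimate("a", 0.1, 0.05), WaldEstimate("b", 0.1, 0.08)]
        assert ivw_scaled(ests).se == pytest.approx(ivw_fixed(ests).se, rel=1e-14)

    def test_se_never_below_fixed(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            ests = [
                WaldEstimate(f"rs{i}", float(rng.normal(0, 0.3)), float(rng.uniform(0.01, 0.3)))
                for i in range(n)
            ]
            assert ivw_scaled(ests).se >= ivw_fixed(ests).se - 1e-15

    def test_single_estimate_raises(self):
        with pytest.raises(EstimationError):
            ivw_scaled([WaldEstimate("a", 0.1, 0.05)])


class TestOrCi:
    def test_null_symmetry(self):
        orp, lo, hi, p = or_ci(0.0, 0.1)
        assert orp == 1.0
        assert lo == pytest.approx(0.822, abs=1e-3)
        assert hi == pytest.approx(1.217, abs=1e-3)
        assert p == pytest.approx(1.0)

    def test_sil2ra_interval(self):
        orp, lo, hi, _ = or_ci(0.19048, 0.04762)
        assert orp == pytest.approx(1.21, abs=0.005)
        assert lo == pytest.approx(1.10, abs=0.005)
        assert hi == pytest.approx(1.33, abs=0.005)

    def test_il6r_single_snp_interval(self):
        # rs56383622: beta 0.03/-0.23 = -0.13043, se 0.02/0.23 = 0.086957
        orp, lo, hi, p = or_ci(0.03 / -0.23, 0.02 / 0.23)
        assert orp == pytest.approx(0.88, abs=0.005)
        assert lo == pytest.approx(0.74, abs=0.005)
        assert hi == pytest.approx(1.04, abs=0.005)
        assert 0.05 < p < 0.20

    def test_bad_level_raises(self):
        with pytest.raises(EstimationError):
            or_ci(0.1, 0.05, level=1.5)


class TestBonferroni:
    def test_family_of_six(self):
        flags = bonferroni_flag([0.0009, 0.027, 0.0083, 0.00834], family_size=6)
        assert flags == [True, False, True, False]  # threshold 0.008333...

    def test_family_one_is_plain_alpha(self):
        assert bonferroni_flag([0.049, 0.051], family_size=1) == [True, False]

    def test_invalid_family_raises(self):
        with pytest.raises(EstimationError):
            bonferroni_flag([0.01], family_size=0)
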