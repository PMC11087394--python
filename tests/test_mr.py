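import math

import numpy as np
import pytest

from mrscreen.errors import DegenerateInstrumentError, NoInstrumentsError
from mrscreen.harmonize import harmonized_from_arrays
from mrscreen.mr import (
    Z95,
    beta_to_or,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    sensitivity,
    wald_ratio,
)

from oracles import egger_oracle, ivw_oracle


def table(bx, by, sey, sex=None):
    bx = np.asarray(bx, float)
    sex = np.full_like(bx, 0.02) if sex is None else np.asarray(sex, float)
    return harmonized_from_arrays(bx, sex, by, sey)


def random_table(rng, n):
    bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
    sex = rng.uniform(0.005, 0.05, n)
    sey = rng.uniform(0.005, 0.05, n)
    by = 0.3 * bx + rng.normal(0, sey)
    return table(bx, by, sey, sex)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.1, 0.02, 0.02, 0.01)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.n_snps == 1

    def test_null_outcome_effect_gives_or_one(self):
        est = wald_ratio(0.1, 0.02, 0.0, 0.01)
        assert est.beta == 0.0
        assert est.or_ == 1.0
        assert est.pval == 1.0

    def test_antisymmetric_in_instrument_sign(self):
        pos = wald_ratio(0.1, 0.02, 0.02, 0.01)
        neg = wald_ratio(-0.1, 0.02, 0.02, 0.01)
        assert neg.beta == -pos.beta
        assert neg.se == pos.se

    def test_zero_exposure_effect_is_typed_error(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.02, 0.02, 0.01)


class TestIVW:
    def test_single_snp_equals_wald_ratio_bit_for_bit(self):
        h = table([0.13], [0.021], [0.011], [0.017])
        assert ivw(h) == wald_ratio(0.13, 0.017, 0.021, 0.011)

    def test_two_snp_hand_computed_value(self):
        # weights 100 and 400; beta = (10+80)/500 = 0.18, se = sqrt(1/500)
        h = table([0.1, 0.2], [0.01, 0.04], [0.01, 0.01])
        est = ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.18, abs=1e-12)
        assert est.se == pytest.approx(math.sqrt(1 / 500), abs=1e-12)

    def test_consensus_ratio_recovered_regardless_of_weights(self, rng):
        bx = rng.uniform(0.1, 0.5, 8)
        c = -0.37
        h = table(bx, c * bx, rng.uniform(0.005, 0.05, 8))
        for mode in ("fixed", "multiplicative_random"):
            assert ivw(h, mode).beta == pytest.approx(c, abs=1e-12)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(50):
            h = random_table(rng, int(rng.integers(2, 30)))
            beta_o, se_fe_o, se_mre_o = ivw_oracle(
                h.rows["beta_exposure"], h.rows["beta_outcome"], h.rows["se_outcome"])
            fe = ivw(h, "fixed")
            mre = ivw(h, "multiplicative_random")
            assert fe.beta == pytest.approx(beta_o, abs=1e-10)
            assert fe.se == pytest.approx(se_fe_o, abs=1e-10)
            assert mre.se == pytest.approx(se_mre_o, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = random_table(rng, 10)
            assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se

    def test_estimate_invariant_under_row_reordering(self, rng):
        h = random_table(rng, 12)
        ref = ivw(h)
        shuffled = h.rows.sample(frac=1.0, random_state=7).reset_index(drop=True)
        h2 = harmonized_from_arrays(shuffled["beta_exposure"], shuffled["se_exposure"],
                                    shuffled["beta_outcome"], shuffled["se_outcome"])
        est = ivw(h2)
        assert est.beta == ref.beta and est.se == ref.se

    def test_empty_table_is_typed_error(self):
        with pytest.raises(NoInstrumentsError):
            ivw(table([], [], []))

    def test_ci_brackets_estimate(self, rng):
        est = ivw(random_table(rng, 5))
        assert est.ci_low < est.beta < est.ci_high
        assert est.or_ == pytest.approx(math.exp(est.beta))
        assert est.or_ci_low == pytest.approx(math.exp(est.ci_low))


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = table(bx, 0.5 * bx, [0.01, 0.01, 0.01])
        q, df, p = cochran_q(h, ivw(h, "fixed").beta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_snp_hand_computation(self):
        # ratios 0.1 and 0.2 about beta 0.18: Q = 100*0.08^2 + 400*0.02^2 = 0.8
        h = table([0.1, 0.2], [0.01, 0.04], [0.01, 0.01])
        q, df, p = cochran_q(h, 0.18)
        assert q == pytest.approx(0.8, abs=1e-12)
        assert df == 1

    def test_doubling_outcome_se_quarters_q(self, rng):
        h = random_table(rng, 8)
        beta = ivw(h, "fixed").beta
        q1, _, _ = cochran_q(h, beta)
        h2 = harmonized_from_arrays(h.rows["beta_exposure"], h.rows["se_exposure"],
                                    h.rows["beta_outcome"], 2 * h.rows["se_outcome"])
        q2, _, _ = cochran_q(h2, ivw(h2, "fixed").beta)
        assert q2 == pytest.approx(q1 / 4, rel=1e-10)

    def test_absent_below_two_snps(self):
        assert cochran_q(table([0.1], [0.02], [0.01]), 0.2) is None


class TestEgger:
    def test_exact_proportional_fit_recovers_slope_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(table(bx, 0.5 * bx, [0.01, 0.02, 0.01, 0.03]))
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_exact_affine_fit_recovers_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(table(bx, 0.02 + 0.5 * bx, [0.01, 0.02, 0.01, 0.03]))
        assert res.intercept == pytest.approx(0.02, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            h = random_table(rng, 10)
            i_o, s_o, se_i_o, se_s_o = egger_oracle(
                h.rows["beta_exposure"], h.rows["beta_outcome"], h.rows["se_outcome"])
            res = egger(h)
            assert res.intercept == pytest.approx(i_o, abs=1e-10)
            assert res.slope.beta == pytest.approx(s_o, abs=1e-10)
            assert res.intercept_se == pytest.approx(se_i_o, abs=1e-10)
            assert res.slope.se == pytest.approx(se_s_o, abs=1e-10)

    def test_orientation_invariant_to_instrument_sign_flips(self, rng):
        h = random_table(rng, 10)
        ref = egger(h)
        sign = rng.choice([-1.0, 1.0], 10)
        h2 = harmonized_from_arrays(sign * h.rows["beta_exposure"], h.rows["se_exposure"],
                                    sign * h.rows["beta_outcome"], h.rows["se_outcome"])
        res = egger(h2)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-12)
        assert res.slope.beta == pytest.approx(ref.slope.beta, abs=1e-12)

    def test_absent_below_three_snps(self):
        assert egger(table([0.1, 0.2], [0.02, 0.03], [0.01, 0.01])) is None


class TestLeaveOneOut:
    def test_identical_snps_leave_estimate_unchanged(self):
        h = table([0.2, 0.2, 0.2], [0.04, 0.04, 0.04], [0.01, 0.01, 0.01])
        full = ivw(h)
        loo = leave_one_out(h)
        assert len(loo) == 3
        for _, est in loo:
            assert est.beta == pytest.approx(full.beta, abs=1e-14)

    def test_outlier_omission_moves_estimate_most(self, rng):
        bx = rng.uniform(0.2, 0.4, 10)
        by = 0.5 * bx
        by[3] += 0.5  # gross outlier
        h = table(bx, by, np.full(10, 0.01))
        full = ivw(h, "fixed")
        shifts = {vid: abs(est.beta - full.beta) for vid, est in leave_one_out(h, "fixed")}
        assert max(shifts, key=shifts.get) == h.rows["variant_id"].iat[3]

    def test_two_snp_reduction_to_wald_ratios(self):
        h = table([0.1, 0.2], [0.01, 0.04], [0.01, 0.01], [0.02, 0.03])
        loo = dict(leave_one_out(h))
        assert loo["snp0"] == wald_ratio(0.2, 0.03, 0.04, 0.01)
        assert loo["snp1"] == wald_ratio(0.1, 0.02, 0.01, 0.01)

    def test_empty_below_two_snps(self):
        assert leave_one_out(table([0.1], [0.02], [0.01])) == []


class TestBetaToOr:
    def test_null_effect_is_or_one(self):
        assert beta_to_or(0.0, 0.1)[0] == 1.0

    def test_log_two_with_zero_se_degenerate_ci(self):
        or_, lo, hi = beta_to_or(math.log(2), 0.0)
        assert or_ == pytest.approx(2.0)
        assert (lo, hi) == (or_, or_)

    def test_reconstructs_printed_eczema_asthma_row(self):
        # published row: OR 1.0861, 95% CI 1.0488-1.1246; beta/se recovered
        # from the printed numbers as ln(OR) and CI-width/(2*1.959964)
        beta = math.log(1.0861)
        se = (math.log(1.1246) - math.log(1.0488)) / (2 * Z95)
        or_, lo, hi = beta_to_or(beta, se)
        assert or_ == pytest.approx(1.0861, abs=1.5e-4)
        assert lo == pytest.approx(1.0488, abs=1.5e-4)
        assert hi == pytest.approx(1.1246, abs=1.5e-4)


class TestSensitivityReport:
    def test_full_battery_at_adequate_snp_count(self, rng):
        h = random_table(rng, 6)
        est = ivw(h)
        rep = sensitivity(h, est)
        assert rep.q_df == 5
        assert rep.q_stat >= 0
        assert rep.egger_intercept is not None
        assert len(rep.loo) == 6

    def test_graceful_absence_below_thresholds(self):
        h = table([0.1], [0.02], [0.01])
        rep = sensitivity(h, ivw(h))
        assert rep.q_stat is None and rep.egger_intercept is None and rep.loo == []
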