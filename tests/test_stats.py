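"""Unit, oracle and property tests for the trial statistics."""

import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmttrial.errors import ConfigError, EstimationError
from gdmttrial.stats import (
    chi_square_2x2,
    consult_rate_test,
    cox_time_to_omt,
    cumulative_incidence,
    enrollment_with_dropout,
    hodges_lehmann,
    interaction_test,
    mann_whitney,
    mc_power_two_group_t,
    nps_summary,
    percent,
    power_two_group_t,
    rank_sum_effect,
    sample_size_two_group_t,
)


def brute_force_mw_p(x, y):
    """Exact two-sided p by enumerating every relabelling of the pooled data."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for idx in combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(a > b for a in xs for b in ys))
    us = np.asarray(us)
    return min(1.0, 2 * min(np.mean(us <= obs), np.mean(us >= obs)))


class TestMannWhitney:
    def test_separated_triples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2], [1, 2])
        assert p == 1.0
        _, p = mann_whitney([3, 3, 3], [3, 3])
        assert p == 1.0

    def test_shifted_pairs_attain_minimum_p(self):
        _, p = mann_whitney([1, 2], [11, 12])
        assert p == pytest.approx(2 / math.comb(4, 2))  # smallest possible at n=(2,2)

    def test_empty_sample_rejected(self):
        with pytest.raises(EstimationError):
            mann_whitney([], [1.0])

    @given(data=st.data())
    def test_exact_p_equals_brute_force_enumeration(self, data):
        n = data.draw(st.integers(2, 5))
        m = data.draw(st.integers(2, 5))
        values = data.draw(st.permutations(range(20)))
        x = np.asarray(values[:n], dtype=float)
        y = np.asarray(values[n:n + m], dtype=float)
        _, p = mann_whitney(x, y, method="exact")
        assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    @given(data=st.data())
    def test_exact_p_matches_scipy(self, data):
        n = data.draw(st.integers(2, 8))
        m = data.draw(st.integers(2, 8))
        values = data.draw(st.permutations(range(30)))
        x = np.asarray(values[:n], dtype=float)
        y = np.asarray(values[n:n + m], dtype=float)
        u, p = mann_whitney(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert u == ref.statistic and p == pytest.approx(ref.pvalue, abs=1e-12)


class TestHodgesLehmann:
    def test_unit_shift_of_triples(self):
        shift, _, _ = hodges_lehmann([1, 2, 3], [2, 3, 4])
        assert shift == 1.0

    def test_no_shift_when_samples_equal(self):
        shift, lo, hi = hodges_lehmann([1, 2, 3], [1, 2, 3])
        assert shift == 0.0 and lo <= 0.0 <= hi

    @given(c=st.floats(-50, 50), data=st.data())
    def test_translation_equivariance(self, c, data):
        x = np.asarray(data.draw(
            st.lists(st.floats(-10, 10), min_size=3, max_size=12)))
        shift0, lo0, hi0 = hodges_lehmann(x, x)
        shift1, lo1, hi1 = hodges_lehmann(x, x + c)
        assert shift1 == pytest.approx(shift0 + c, abs=1e-9)
        assert lo1 == pytest.approx(lo0 + c, abs=1e-9)
        assert hi1 == pytest.approx(hi0 + c, abs=1e-9)

    def test_ci_contains_estimate_and_narrows_with_alpha(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 25)
        y = rng.normal(1, 1, 30)
        widths = []
        for alpha in (0.01, 0.05, 0.2):
            shift, lo, hi = hodges_lehmann(x, y, alpha=alpha)
            assert lo <= shift <= hi
            widths.append(hi - lo)
        assert widths[0] >= widths[1] >= widths[2]

    def test_large_sample_ci_covers_true_shift(self):
        # normal-approximation branch (n*m > 400), repeated-coverage check
        rng = np.random.default_rng(11)
        cover = 0
        for _ in range(300):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0.5, 1, 40)
            _, lo, hi = hodges_lehmann(x, y)
            cover += lo <= 0.5 <= hi
        assert 0.92 <= cover / 300 <= 0.99

    def test_effect_estimate_wrapper(self):
        eff = rank_sum_effect([0.0, 0.1, 0.2], [1.0, 1.1, 1.2])
        assert eff.shift == pytest.approx(1.0)
        assert eff.median_difference == pytest.approx(1.0)
        assert eff.ci_low <= eff.shift <= eff.ci_high
        assert eff.n_a == eff.n_b == 3


class TestChiSquare:
    def test_direct_formula(self):
        stat, p = chi_square_2x2(22, 56, 5, 67)
        a, b, c, d = 22, 56, 5, 67
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(11.47, abs=0.01)
        assert p < 0.001

    def test_independence_gives_zero(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_perfect_association(self):
        stat, p = chi_square_2x2(5, 0, 0, 5)
        assert stat == pytest.approx(10.0) and p < 0.05

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(1, 30))
    def test_invariance_under_row_and_column_swaps(self, a, b, c, d):
        stat, _ = chi_square_2x2(a, b, c, d)
        assert chi_square_2x2(c, d, a, b)[0] == pytest.approx(stat)  # rows
        assert chi_square_2x2(b, a, d, c)[0] == pytest.approx(stat)  # columns

    def test_zero_margin_signalled(self):
        with pytest.raises(EstimationError, match="margin"):
            chi_square_2x2(0, 0, 3, 4)

    def test_yates_toggle_reduces_statistic(self):
        plain, _ = chi_square_2x2(12, 5, 6, 12)
        yates, _ = chi_square_2x2(12, 5, 6, 12, continuity=True)
        assert yates < plain


class TestConsultRates:
    def test_identical_counts_give_ratio_one(self):
        counts = [2, 1, 3, 0, 2, 4, 1, 2]
        r = consult_rate_test(counts, counts)
        assert r.rate_ratio == pytest.approx(1.0)
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_null_poisson_coverage(self):
        rng = np.random.default_rng(3)
        covered = 0
        n_reps = 300
        for _ in range(n_reps):
            a = rng.poisson(2.0, 200)
            b = rng.poisson(2.0, 200)
            r = consult_rate_test(a, b)
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert covered / n_reps >= 0.93

    def test_overdispersed_counts_use_negative_binomial(self):
        rng = np.random.default_rng(4)
        a = rng.negative_binomial(1, 0.2, 300)  # variance >> mean
        b = rng.negative_binomial(1, 0.25, 300)
        r = consult_rate_test(a, b)
        assert r.model_used == "negative_binomial"
        assert r.dispersion > 1.5

    def test_equidispersed_counts_stay_poisson(self):
        rng = np.random.default_rng(5)
        r = consult_rate_test(rng.poisson(2, 300), rng.poisson(2.4, 300))
        assert r.model_used == "poisson"

    def test_all_zero_counts_signalled(self):
        with pytest.raises(EstimationError):
            consult_rate_test([0, 0, 0], [0, 0, 0])


class TestCox:
    @staticmethod
    def simulate(rng, n, hr, censor=0.8):
        t1 = rng.exponential(1.0 / hr, n)
        t0 = rng.exponential(1.0, n)
        t = np.concatenate([t0, t1])
        e = t < censor
        return np.minimum(t, censor) + 1e-9, e, np.r_[np.zeros(n), np.ones(n)]

    def test_parameter_recovery_hr_4_5(self):
        rng = np.random.default_rng(7)
        t, e, z = self.simulate(rng, 500, 4.5)
        r = cox_time_to_omt(t, e, z)
        assert abs(r.hazard_ratio - 4.5) / 4.5 < 0.2
        assert r.ci_low < r.hazard_ratio < r.ci_high

    def test_null_z_scores_are_calibrated(self):
        rng = np.random.default_rng(8)
        inside = 0
        n_reps = 100
        for _ in range(n_reps):
            t, e, z = self.simulate(rng, 150, 1.0)
            r = cox_time_to_omt(t, e, z)
            inside += abs(r.log_hr / r.se) < 2
        assert inside / n_reps >= 0.9

    def test_matches_lifelines_on_tie_free_data(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        t, e, z = self.simulate(rng, 120, 2.0)
        mine = cox_time_to_omt(t, e, z)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "z": z}), "t", "e")
        # Efron and Breslow coincide without ties
        assert mine.log_hr == pytest.approx(float(cph.params_["z"]), abs=1e-5)
        assert mine.se == pytest.approx(float(cph.standard_errors_["z"]), abs=1e-5)

    def test_no_events_signalled(self):
        with pytest.raises(EstimationError, match="no events"):
            cox_time_to_omt([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])

    def test_events_in_one_arm_only_signalled(self):
        with pytest.raises(EstimationError, match="one arm"):
            cox_time_to_omt([1.0, 5.0, 5.0, 5.0], [1, 0, 0, 0], [1, 1, 0, 0])


class TestCumulativeIncidence:
    def test_no_events_identically_zero(self):
        ci = cumulative_incidence([5, 6, 7], [0, 0, 0])
        assert (ci["incidence"] == 0.0).all()

    def test_all_events_jump_to_one(self):
        ci = cumulative_incidence([1, 1, 1], [1, 1, 1])
        assert ci.loc[ci["time"] == 1.0, "incidence"].iloc[0] == 1.0

    def test_half_events_reach_half(self):
        ci = cumulative_incidence([1, 1, 5, 5], [1, 1, 0, 0])
        assert ci.loc[ci["time"] == 1.0, "incidence"].iloc[0] == pytest.approx(0.5)

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(10)
        ci = cumulative_incidence(rng.exponential(1, 50),
                                  rng.random(50) < 0.7)
        assert (np.diff(ci["incidence"]) >= -1e-12).all()


class TestInteraction:
    def test_equal_effects_give_t_zero_p_one(self):
        t, p = interaction_test(1.3, 0.4, 1.3, 0.5)
        assert t == 0.0 and p == 1.0

    def test_forced_arithmetic(self):
        t, p = interaction_test(1.0, 0.5, 0.0, 0.5)
        assert t == pytest.approx(math.sqrt(2))
        assert p == pytest.approx(2 * sps.norm.sf(math.sqrt(2)))

    def test_swapping_groups_flips_sign_same_p(self):
        t1, p1 = interaction_test(0.8, 0.3, 0.2, 0.4)
        t2, p2 = interaction_test(0.2, 0.4, 0.8, 0.3)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_zero_se_signalled(self):
        with pytest.raises(EstimationError):
            interaction_test(1.0, 0.0, 0.5, 0.2)


class TestNPS:
    def test_single_promoter(self):
        s = nps_summary([9])
        assert s.promoters == 1 and s.nps == 100.0

    def test_passives_cancel(self):
        assert nps_summary([7, 8]).nps == 0.0

    def test_classification_of_mixed_panel(self):
        scores = [9] * 4 + [10] * 3 + [7] * 6 + [8] * 5 + [6, 5, 4, 3, 2, 1]
        s = nps_summary(scores)
        assert (s.promoters, s.passives, s.detractors) == (7, 11, 6)
        assert s.nps == pytest.approx(100 * (7 - 6) / 24)
        assert s.n == 24

    def test_empty_or_out_of_range_signalled(self):
        with pytest.raises(EstimationError):
            nps_summary([])
        with pytest.raises(EstimationError):
            nps_summary([0, 5])


class TestDesign:
    def test_protocol_sample_size(self):
        assert sample_size_two_group_t(0.36, 0.76, 0.80, 0.05) == 71

    def test_enrollment_with_dropout(self):
        assert enrollment_with_dropout(71, 0.05) == 150
        assert enrollment_with_dropout(71, 0.0) == 142
        assert enrollment_with_dropout(1, 0.5) == 4

    def test_tiny_variance_floors_at_two(self):
        assert sample_size_two_group_t(1.0, 1e-6, 0.80, 0.05) == 2

    def test_power_round_trip_and_monotonicity(self):
        n = sample_size_two_group_t(0.36, 0.76, 0.80, 0.05)
        assert power_two_group_t(n, 0.36, 0.76) >= 0.80
        assert power_two_group_t(n - 1, 0.36, 0.76) < power_two_group_t(n, 0.36, 0.76)
        assert power_two_group_t(n - 1, 0.36, 0.76) < 0.80

    def test_noncentral_t_power_agrees_with_monte_carlo(self):
        exact = power_two_group_t(30, 0.5, 1.0)
        mc = mc_power_two_group_t(30, 0.5, 1.0, n_reps=20000, seed=12)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_invalid_settings_signalled(self):
        with pytest.raises(ConfigError):
            sample_size_two_group_t(-1.0, 1.0)
        with pytest.raises(ConfigError):
            sample_size_two_group_t(0.5, 1.0, power=1.5)
        with pytest.raises(ConfigError):
            enrollment_with_dropout(71, 1.0)


class TestPercent:
    @pytest.mark.parametrize("count,total,expected", [
        (22, 78, 28.2), (5, 72, 6.9), (25, 78, 32.1),
        (16, 24, 66.7), (18, 22, 81.8),
    ])
    def test_one_decimal_rounding(self, count, total, expected):
        assert percent(count, total) == expected
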