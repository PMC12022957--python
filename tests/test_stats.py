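"""Statistical layer: oracles by brute force, printed-value checks,
symmetries."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from sixmwt.stats import (ContingencyTable2x2, chi2_test, effect_label,
                          hedges_g, mann_whitney_u, mean_percentage_change,
                          odds_ratio, sample_size, summarize,
                          wilcoxon_paired)


class TestSummarize:
    def test_hand_computed_summary(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.mean == 3.0
        assert s.sd == pytest.approx(1.5811, abs=1e-4)
        assert s.median == 3.0
        assert (s.iqr_low, s.iqr_high) == (2.0, 4.0)
        # t-based CI: 3 ± 2.7764·1.5811/√5
        assert s.ci95_low == pytest.approx(3 - 2.7764 * 1.5811 / 5**0.5,
                                           abs=1e-3)
        assert s.ci95_low <= s.mean <= s.ci95_high

    def test_constant_sample_degenerates(self):
        s = summarize([7.0] * 6)
        assert s.sd == 0.0
        assert s.ci95_low == s.ci95_high == 7.0
        assert s.distribution_normal

    def test_normality_gate(self):
        rng = np.random.default_rng(3)
        assert summarize(rng.normal(size=200)).distribution_normal
        assert not summarize(rng.lognormal(0, 1.5, size=200)
                             ).distribution_normal

    def test_too_small(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestMannWhitney:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, list(x))
        assert u == len(x) ** 2 / 2
        assert p > 0.9

    def test_complete_separation(self):
        x = [10, 11, 12, 13, 14]
        y = [1, 2, 3, 4, 5]
        u, p = mann_whitney_u(x, y)
        assert u == 25
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_u_matches_pairwise_count_oracle(self):
        """U equals #(x_i > y_j) + ties/2, exhaustively, for n ≤ 6."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            nx, ny = rng.integers(1, 7, size=2)
            x = rng.integers(0, 8, size=nx).astype(float)
            y = rng.integers(0, 8, size=ny).astype(float)
            u, _ = mann_whitney_u(x, y)
            oracle = sum((xi > yj) + 0.5 * (xi == yj)
                         for xi in x for yj in y)
            assert u == pytest.approx(oracle)

    def test_exact_p_matches_permutation_enumeration(self):
        """Exact two-sided p agrees with enumerating all rank splits."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pool = rng.permutation(nx + ny)[: nx + ny].astype(float)
            x, y = pool[:nx], pool[nx:]
            u_obs, p = mann_whitney_u(x, y)
            mu = nx * ny / 2
            us = []
            for comb in itertools.combinations(range(nx + ny), nx):
                xs = pool[list(comb)]
                ys = np.delete(pool, list(comb))
                us.append(sum((xi > yj) for xi in xs for yj in ys))
            us = np.array(us, dtype=float)
            p_oracle = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_u_sum_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            nx, ny = rng.integers(2, 30, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            ux, _ = mann_whitney_u(x, y)
            uy, _ = mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(nx * ny)

    def test_exact_and_asymptotic_agree(self):
        """Within 0.02 for tie-free samples of at least 8 per group."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(8, 15)))
            y = rng.normal(size=int(rng.integers(8, 15)))
            _, pe = mann_whitney_u(x, y, method="exact")
            _, pa = mann_whitney_u(x, y, method="asymptotic")
            assert abs(pe - pa) < 0.02

    def test_ties_fall_back_to_corrected_normal(self):
        x = [1, 2, 2, 3.0]
        y = [2, 3, 3, 4.0]
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)
        with pytest.raises(ValueError):
            mann_whitney_u(x, y, method="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChi2:
    def test_proportional_table_is_null(self):
        res = chi2_test(ContingencyTable2x2(10, 20, 20, 40))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        """Σ(O−E)²/E computed cell by cell for the 9/26 vs 1/28 table."""
        table = ContingencyTable2x2(9, 17, 1, 27)
        expected = np.outer([26, 28], [10, 44]) / 54
        oracle = float(((np.array([[9, 17], [1, 27]]) - expected) ** 2
                        / expected).sum())
        res = chi2_test(table)
        assert res.statistic == pytest.approx(oracle)
        assert res.low_expected_warning

    def test_study_significance_for_chronotropic_table(self):
        res = chi2_test(ContingencyTable2x2(6, 20, 1, 27))
        assert res.p_value < 0.05
        assert res.p_value == pytest.approx(0.033, abs=5e-4)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_test(ContingencyTable2x2(0, 26, 0, 28))

    def test_yates_correction_shrinks_statistic(self):
        t = ContingencyTable2x2(9, 17, 1, 27)
        assert (chi2_test(t, continuity_correction=True).statistic
                < chi2_test(t).statistic)


class TestWilcoxon:
    def test_no_change_is_degenerate(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_uniform_shift_gives_minimal_p(self):
        before = list(range(1, 11))
        after = [2.0 * b for b in before]    # distinct positive differences
        res = wilcoxon_paired(before, after)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 2**10, rel=1e-9)

    def test_matches_sign_assignment_enumeration(self):
        """Exact p agrees with brute force over all 2^n sign flips."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 8
            d = rng.permutation(np.arange(1, n + 1)) * \
                rng.choice([-1.0, 1.0], size=n)
            before = np.zeros(n)
            res = wilcoxon_paired(before, d)
            ranks = sps.rankdata(np.abs(d))
            w_plus = ranks[d > 0].sum()
            mu = n * (n + 1) / 4
            ws = [sum(r for r, s in zip(ranks, signs) if s)
                  for signs in itertools.product([False, True], repeat=n)]
            p_oracle = np.mean([abs(w - mu) >= abs(w_plus - mu) - 1e-12
                                for w in ws])
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2, 3], [1, 2])


class TestMeanPercentageChange:
    @pytest.mark.parametrize("case, control, expected", [
        (641, 702, -9.516), (5.0, 5.0, 0.0), (-11, 12, 209.091)])
    def test_values(self, case, control, expected):
        assert mean_percentage_change(case, control) == pytest.approx(
            expected, abs=1e-3)

    def test_zero_case_mean_undefined(self):
        with pytest.raises(ZeroDivisionError):
            mean_percentage_change(0.0, 5.0)


class TestOddsRatio:
    def test_printed_tables(self):
        assert odds_ratio(ContingencyTable2x2(9, 17, 1, 27)
                          ).odds_ratio == pytest.approx(243 / 17)
        assert odds_ratio(ContingencyTable2x2(6, 20, 1, 27)
                          ).odds_ratio == pytest.approx(8.1)

    def test_proportional_table_is_unity(self):
        assert odds_ratio(ContingencyTable2x2(5, 10, 10, 20)
                          ).odds_ratio == pytest.approx(1.0)

    def test_row_swap_inverts(self):
        a = odds_ratio(ContingencyTable2x2(9, 17, 1, 27))
        b = odds_ratio(ContingencyTable2x2(1, 27, 9, 17))
        assert a.odds_ratio * b.odds_ratio == pytest.approx(1.0)
        assert a.ci95_low == pytest.approx(1 / b.ci95_high)

    def test_woolf_interval_contains_point(self):
        res = odds_ratio(ContingencyTable2x2(9, 17, 1, 27))
        assert res.ci95_low < res.odds_ratio < res.ci95_high

    def test_zero_cell_policies(self):
        t = ContingencyTable2x2(5, 21, 0, 28)
        with pytest.raises(ValueError):
            odds_ratio(t, "error")
        res = odds_ratio(t, "haldane")
        assert res.haldane_applied
        assert res.odds_ratio == pytest.approx(
            (5.5 * 28.5) / (21.5 * 0.5))


class TestHedgesG:
    def test_printed_moments_reproduce_study_value(self):
        g, label = hedges_g(641, 57, 26, 702, 60, 28)
        assert g == pytest.approx(-1.026, abs=5e-4)
        assert label == "large"

    def test_equal_means_zero_small(self):
        g, label = hedges_g(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert g == 0.0 and label == "small"

    def test_antisymmetric(self):
        g1, _ = hedges_g(10, 2, 12, 8, 3, 15)
        g2, _ = hedges_g(8, 3, 15, 10, 2, 12)
        assert g1 == pytest.approx(-g2)

    def test_shrinks_toward_zero(self):
        """|g| < |raw d| for every finite sample size (J < 1)."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            n1, n2 = rng.integers(2, 60, size=2)
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 3, size=2)
            g, _ = hedges_g(m1, s1, int(n1), m2, s2, int(n2))
            pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2)
                               / (n1 + n2 - 2))
            d = (m1 - m2) / pooled
            assert abs(g) < abs(d) or d == 0

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(ValueError):
            hedges_g(1, 0, 5, 2, 0, 5)

    @pytest.mark.parametrize("g, label", [
        (0.1, "small"), (0.2, "small"), (-0.5, "medium"), (0.65, "medium"),
        (0.8, "large"), (-1.29, "large"), (1.30, "very_large")])
    def test_magnitude_labels(self, g, label):
        assert effect_label(g) == label


class TestSampleSize:
    def test_study_design(self):
        p = sample_size(1.96, 1.28, 1, 50, 31, attrition=0.0)
        assert p.raw_n == pytest.approx(54.62, abs=0.01)
        assert p.n_per_group == 27
        assert p.n_total == 54
        assert p.n_revised == 54

    def test_attrition_revision(self):
        p = sample_size(1.96, 1.28, 1, 50, 31, attrition=0.10)
        assert p.n_revised == 60
        assert p.n_revised >= p.n_total

    def test_doubling_difference_quarters_raw_n(self):
        a = sample_size(1.96, 1.28, 1, 50, 31)
        b = sample_size(1.96, 1.28, 1, 50, 62)
        assert a.raw_n == pytest.approx(4 * b.raw_n)

    def test_zero_difference_rejected(self):
        with pytest.raises(ValueError):
            sample_size(1.96, 1.28, 1, 50, 0)

    def test_unequal_allocation(self):
        p = sample_size(1.96, 1.28, 2, 50, 31)
        assert p.n_case == pytest.approx(2 * p.n_control, abs=1)
        assert p.n_total == p.n_case + p.n_control
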