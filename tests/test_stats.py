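"""Statistical battery: each test against an independent oracle or a
closed-form/simulation property."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twostep.hybrid import TrialRecord
from twostep.stats import (
    DeltaRatios,
    PowerSpec,
    bayes_cor_logbf,
    delta_ratios,
    icc_consistency_average,
    ks_normality,
    paired_contrast,
    paired_ttest_power,
    rank_ancova,
    rm_anova,
    rt_by_transition,
    solve_n,
    stay_probability_table,
    wilcoxon_signed_rank,
)


def long_table(values: np.ndarray, conditions=("control", "LPFC_to_IPS",
                                               "IPS_to_LPFC"),
               order=None) -> pd.DataFrame:
    n, k = values.shape
    rows = []
    for i in range(n):
        for j, cond in enumerate(conditions):
            rows.append({"subject": f"S{i:02d}", "condition": cond,
                         "order": 1 if order is None else order[i],
                         "value": values[i, j]})
    return pd.DataFrame(rows)


class TestNormality:
    def test_gaussian_null_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejected = sum(
            ks_normality(rng.normal(size=200)).pvalue < 0.05 for _ in range(100)
        )
        assert rejected <= 12

    def test_skewed_samples_mostly_fail(self):
        rng = np.random.default_rng(1)
        rejected = sum(
            ks_normality(np.exp(rng.normal(size=29) * 1.2)).pvalue < 0.05
            for _ in range(50)
        )
        assert rejected > 30

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestRmAnova:
    def test_identical_conditions_give_zero_f(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=12)
        tab = long_table(np.tile(base[:, None], (1, 3)))
        res = rm_anova(tab)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_df_accounting_29_by_3(self):
        rng = np.random.default_rng(3)
        tab = long_table(rng.normal(size=(29, 3)))
        res = rm_anova(tab)
        assert res.df == (2.0, 56.0)

    def test_f_grows_with_injected_shift(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(20, 3))
        fs = []
        for shift in (0.0, 0.5, 1.0):
            v = base.copy()
            v[:, 2] += shift
            fs.append(rm_anova(long_table(v)).statistic)
        assert fs[0] < fs[1] < fs[2]

    def test_two_condition_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 15))
        tab = long_table(np.column_stack([x, y]), conditions=("a", "b"))
        f = rm_anova(tab).statistic
        t = paired_contrast(x, y).statistic
        assert f == pytest.approx(t**2, rel=1e-6)

    def test_mixed_anova_reports_order_interaction(self):
        rng = np.random.default_rng(6)
        order = np.repeat([1, 2, 3], 10)
        tab = long_table(rng.normal(size=(30, 3)), order=order)
        res = rm_anova(tab, between="order")
        assert res.df == (2.0, 54.0)
        assert "Interaction" in set(res.table["Source"])

    def test_missing_cell_raises_with_pair_named(self):
        rng = np.random.default_rng(7)
        tab = long_table(rng.normal(size=(8, 3)))
        tab = tab[~((tab.subject == "S03") & (tab.condition == "control"))]
        with pytest.raises(ValueError, match="S03"):
            rm_anova(tab)


class TestPairedContrast:
    def test_identical_vectors_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_contrast(x, x)

    def test_t_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=29)
        y = x - 0.4 + rng.normal(0, 0.3, size=29)
        d = x - y
        expected_t = d.mean() / (d.std(ddof=1) / math.sqrt(29))
        res = paired_contrast(x, y)
        assert res.statistic == pytest.approx(expected_t)
        assert res.df == 28.0

    def test_dual_effect_sizes_reported(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=29)
        y = x - 0.5 + rng.normal(0, 0.5, 29)
        res = paired_contrast(x, y)
        assert 0 < res.effect_sizes["r_t"] < 1
        assert 0 < res.effect_sizes["r_z"] < 1
        # t-based r from its defining identity
        t, df = res.statistic, res.df
        assert res.effect_sizes["r_t"] == pytest.approx(
            math.sqrt(t**2 / (t**2 + df))
        )


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.zeros(5)
        res = wilcoxon_signed_rank(x, y)
        assert res.flags["method"] == "exact"
        assert res.pvalue == pytest.approx(2 / 32)

    def test_antisymmetric_differences_near_null_mean(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = wilcoxon_signed_rank(x, np.zeros(6))
        assert res.statistic == pytest.approx(6 * 7 / 4)  # null mean of W+
        assert res.pvalue == pytest.approx(1.0)

    def test_exact_matches_scipy_enumeration(self):
        """For tie-free data, the convolution-based exact p equals scipy's
        exact Wilcoxon p across many random draws (n <= 12)."""
        rng = np.random.default_rng(10)
        for n in (5, 8, 12):
            for _ in range(20):
                d = rng.normal(0.3, 1.0, size=n)
                d = d[d != 0]
                res = wilcoxon_signed_rank(d, np.zeros_like(d), exact_max_n=12)
                ref = sps.wilcoxon(d, mode="exact")
                assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_approximate_agree_at_moderate_n(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, size=15)
            exact = wilcoxon_signed_rank(d, np.zeros(15), exact_max_n=20)
            approx = wilcoxon_signed_rank(d, np.zeros(15), exact_max_n=0)
            assert abs(exact.pvalue - approx.pvalue) < 0.02

    def test_ties_use_midranks(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0])
        res = wilcoxon_signed_rank(d, np.zeros(5))
        assert res.statistic == pytest.approx(2.0 + 2.0 + 4.5 + 4.5)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))


class TestRankAncova:
    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(12)
        order = np.repeat([1, 2, 3], 4)
        vals = rng.normal(size=(12, 3)) + 2.0
        a = rank_ancova(long_table(vals, order=order))
        b = rank_ancova(long_table(np.exp(vals), order=order))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_power_grows_with_shift(self):
        rng = np.random.default_rng(13)
        order = np.repeat([1, 2, 3], 6)
        base = rng.normal(size=(18, 3))
        fs = []
        for shift in (0.0, 1.0, 2.0):
            v = base.copy()
            v[:, 2] += shift
            fs.append(rank_ancova(long_table(v, order=order)).statistic)
        assert fs[0] < fs[1] < fs[2]

    def test_quade_matches_r_reference(self):
        # frozen oracle: R stats::quade.test on this matrix gives
        # F = 7.1135, df = (2, 10), p = 0.01198
        m = np.array([[31, 27, 24], [31, 28, 31], [45, 29, 46],
                      [21, 18, 48], [42, 36, 46], [32, 17, 40]], dtype=float)
        res = rank_ancova(long_table(m), method="quade")
        assert res.statistic == pytest.approx(7.1135, abs=1e-3)
        assert res.df == (2, 10)
        assert res.pvalue == pytest.approx(0.01198, abs=1e-4)


class TestICC:
    def test_additive_column_shift_gives_unity(self):
        rng = np.random.default_rng(14)
        col = rng.normal(size=10)
        m = np.column_stack([col, col + 1.0, col - 0.5])
        res = icc_consistency_average(m)
        assert res.statistic == pytest.approx(1.0)

    def test_pure_noise_averages_near_zero(self):
        rng = np.random.default_rng(15)
        vals = [icc_consistency_average(rng.normal(size=(20, 3))).statistic
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.1

    def test_hand_worked_anova_decomposition(self):
        m = np.array([[1.0, 2.0, 3.0],
                      [2.0, 4.0, 5.0],
                      [5.0, 6.0, 9.0],
                      [3.0, 3.0, 4.0]])
        n, k = m.shape
        grand = m.mean()
        ms_subj = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        ms_sess = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        ms_err = (((m - grand) ** 2).sum()
                  - (n - 1) * ms_subj - (k - 1) * ms_sess) / ((n - 1) * (k - 1))
        res = icc_consistency_average(m)
        assert res.statistic == pytest.approx((ms_subj - ms_err) / ms_subj)

    def test_matches_pingouin_icc3k(self):
        import pingouin as pg

        rng = np.random.default_rng(16)
        m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        res = icc_consistency_average(m)
        df = pd.DataFrame(
            [(i, j, m[i, j]) for i in range(12) for j in range(3)],
            columns=["s", "r", "y"],
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        icc3k = float(ref.loc[ref["Type"] == "ICC(C,k)", "ICC"].iloc[0])
        assert res.statistic == pytest.approx(icc3k, abs=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            icc_consistency_average(m)


class TestBayesCorrelation:
    def test_null_sample_favours_null(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        y -= y.dot(x) / x.dot(x) * x  # exactly uncorrelated with x
        res = bayes_cor_logbf(x, y)
        assert res.statistic < 0

    def test_strong_effect_favours_alternative(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=30)
        y = 0.9 * x + 0.3 * rng.normal(size=30)
        assert bayes_cor_logbf(x, y).statistic > 0

    def test_matches_pingouin_closed_form(self):
        import pingouin as pg

        rng = np.random.default_rng(19)
        for _ in range(5):
            x = rng.normal(size=25)
            y = 0.4 * x + rng.normal(size=25)
            mine = bayes_cor_logbf(x, y)
            ref = math.log(pg.bayesfactor_pearson(mine.effect_sizes["r"], 25))
            assert mine.statistic == pytest.approx(ref, abs=0.02)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            bayes_cor_logbf([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])


class TestPower:
    def test_study_sample_size(self):
        assert solve_n(PowerSpec(dz=0.7, alpha=0.05, power=0.95)) == 29

    def test_null_effect_power_equals_alpha(self):
        for n in (5, 20, 80):
            p = paired_ttest_power(PowerSpec(dz=0.0, alpha=0.05, power=0.5, n=n))
            assert p == pytest.approx(0.05, abs=1e-6)

    def test_power_nondecreasing_in_n(self):
        powers = [paired_ttest_power(PowerSpec(0.5, n=n)) for n in range(5, 60, 5)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_no_finite_n_signalled(self):
        with pytest.raises(ValueError, match="no finite n"):
            solve_n(PowerSpec(dz=0.0, alpha=0.05, power=0.5))


def alternating_trials(n=40):
    """A deterministic repeater covering all four previous-outcome cells."""
    trials = []
    combos = itertools.cycle([(1, True), (1, False), (0, True), (0, False)])
    for _ in range(n):
        reward, common = next(combos)
        trials.append(TrialRecord(0, 0 if common else 1, 0, reward, common))
    return trials


class TestStaySignatures:
    def test_always_repeat_agent_has_unit_cells(self):
        table = stay_probability_table(alternating_trials())
        assert np.allclose(table.probs.to_numpy(), 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            stay_probability_table(alternating_trials(2)[:1])


class TestRtByTransition:
    @staticmethod
    def rt_frame(rng, n_subjects=12, slowing=0.0):
        rows = []
        for i in range(n_subjects):
            for t in range(60):
                common = t % 3 != 0
                rt = rng.normal(700, 50) + (0 if common else slowing)
                rows.append({"subject": f"S{i}", "valid": 1,
                             "transition": "common" if common else "rare",
                             "rt2_ms": rt})
        return pd.DataFrame(rows)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(20)
        res = rt_by_transition(self.rt_frame(rng))
        assert abs(res.effect_sizes["mean_slowing_ms"]) < 15

    def test_injected_slowing_recovered(self):
        rng = np.random.default_rng(21)
        res = rt_by_transition(self.rt_frame(rng, slowing=100.0))
        assert res.effect_sizes["mean_slowing_ms"] == pytest.approx(100.0, abs=15)
        assert res.pvalue < 0.001

    def test_subject_without_rare_trials_excluded(self):
        rng = np.random.default_rng(22)
        df = self.rt_frame(rng)
        df = df[~((df.subject == "S0") & (df.transition == "rare"))]
        res = rt_by_transition(df)
        assert "S0" in res.flags["excluded_subjects"]


class TestDeltaRatios:
    def test_equal_inputs_give_unity(self):
        r = delta_ratios([0.4], [0.4], [2.0], [2.0])
        assert r.delta_w[0] == 1.0 and r.delta_p[0] == 1.0

    def test_direct_arithmetic(self):
        r = delta_ratios([0.3], [0.6], [1.0], [2.0])
        assert r.delta_w[0] == pytest.approx(0.5)
        assert r.delta_p[0] == pytest.approx(2.0)

    def test_zero_denominator_flagged_missing(self):
        r = delta_ratios([0.3], [0.6], [0.0], [2.0])
        assert np.isnan(r.delta_p[0]) and r.flagged[0]
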