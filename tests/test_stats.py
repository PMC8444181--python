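import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import SEED
from siginfo.exceptions import DegenerateDataError
from siginfo.stats import (
    anova_1way,
    anova_nway,
    center_scale,
    classify_effect,
    cohens_d_unbiased,
    compare_groups,
    compare_replicate_correlations,
    ks_normality,
    pearson_correlation,
    significance_decision,
)


class TestCenterScale:
    def test_each_group_standardised(self, rng):
        values = np.concatenate([rng.normal(5, 2, 20), rng.normal(-3, 0.5, 30)])
        labels = np.array(["a"] * 20 + ["b"] * 30)
        z = center_scale(values, labels)
        for g in ("a", "b"):
            grp = z[labels == g]
            assert grp.mean() == pytest.approx(0.0, abs=1e-12)
            assert grp.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_within_group_rank_order_preserved(self, rng):
        values = rng.normal(size=15)
        z = center_scale(values, np.zeros(15))
        assert np.array_equal(np.argsort(values), np.argsort(z))

    def test_constant_group_names_the_group(self):
        with pytest.raises(DegenerateDataError, match="flat"):
            center_scale([1.0, 1.0, 2.0, 3.0], ["flat", "flat", "g", "g"])


class TestKsNormality:
    def test_normal_sample_passes(self, rng):
        z = center_scale(rng.normal(size=1000), np.zeros(1000))
        _, p = ks_normality(z)
        assert p > 0.05

    def test_uniform_sample_fails(self, rng):
        z = center_scale(rng.uniform(0, 1, 1000), np.zeros(1000))
        _, p = ks_normality(z)
        assert p < 0.01

    def test_statistic_in_unit_interval(self, rng):
        stat, _ = ks_normality(rng.normal(size=50))
        assert 0 <= stat <= 1


class TestAnovaNway:
    @staticmethod
    def _design(rng, genotype_shift=0.0):
        rows = []
        for g in ("wt", "mut"):
            for dose in (0.0, 10.0, 150.0):
                for rep in range(4):
                    y = rng.normal() + (genotype_shift if g == "mut" else 0.0)
                    rows.append({"genotype": g, "dose_ng_ml": dose, "mi_bits": y})
        return pd.DataFrame(rows)

    def test_null_design_has_large_p(self):
        df = self._design(np.random.default_rng(SEED))
        table = anova_nway(df, "mi_bits", ["genotype", "dose_ng_ml"])
        assert (table["p"] > 0.05).all()

    def test_shifted_genotype_detected(self):
        df = self._design(np.random.default_rng(SEED), genotype_shift=3.0)
        table = anova_nway(df, "mi_bits", ["genotype", "dose_ng_ml"]).set_index("factor")
        assert table.loc["genotype", "p"] < 0.01
        assert table.loc["dose_ng_ml", "p"] > 0.05

    def test_factor_order_immaterial_in_balanced_design(self):
        df = self._design(np.random.default_rng(SEED), genotype_shift=1.0)
        a = anova_nway(df, "mi_bits", ["genotype", "dose_ng_ml"]).set_index("factor")
        b = anova_nway(df, "mi_bits", ["dose_ng_ml", "genotype"]).set_index("factor")
        for f in ("genotype", "dose_ng_ml"):
            assert a.loc[f, "F"] == pytest.approx(b.loc[f, "F"], rel=1e-9)

    def test_single_level_factor_rejected(self):
        df = self._design(np.random.default_rng(SEED))
        with pytest.raises(ValueError):
            anova_nway(df[df["genotype"] == "wt"], "mi_bits", ["genotype"])


class TestAnova1way:
    def test_identical_groups(self):
        F, p = anova_1way([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert F == 0.0 and p == 1.0

    def test_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        F, p_f = anova_1way(a, b)
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_symmetric_in_groups(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert anova_1way(a, b) == pytest.approx(anova_1way(b, a))

    def test_all_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            anova_1way([2.0, 2.0], [2.0, 2.0])


def d_unb_by_hand(A, B):
    """Direct re-evaluation of the printed formulas with plain Python floats."""
    mA = sum(A) / len(A)
    mB = sum(B) / len(B)
    ssA = sum((x - mA) ** 2 for x in A)
    ssB = sum((x - mB) ** 2 for x in B)
    s = math.sqrt((ssA + ssB) / ((len(A) - 1) + (len(B) - 1)))
    return (mA - mB) / s


class TestCohensD:
    def test_worked_example(self):
        eff = cohens_d_unbiased([2.0, 4.0], [1.0, 3.0])
        assert eff.m_A == 3.0 and eff.m_B == 2.0
        assert eff.SS_A == 2.0 and eff.SS_B == 2.0
        assert eff.s_AB == pytest.approx(math.sqrt(2))
        assert eff.d_unb == pytest.approx(1 / math.sqrt(2))

    def test_identical_groups_give_zero(self):
        assert cohens_d_unbiased([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]).d_unb == 0.0

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
        d1 = cohens_d_unbiased(a, b).d_unb
        d2 = cohens_d_unbiased(4.2 * a, 4.2 * b).d_unb
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_zero_pooled_scale_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d_unbiased([1.0, 1.0], [3.0, 3.0])

    @settings(max_examples=2000, deadline=None, derandomize=True, database=None)
    @given(
        A=st.lists(st.integers(-9, 9), min_size=2, max_size=8),
        B=st.lists(st.integers(-9, 9), min_size=2, max_size=8),
    )
    def test_fuzz_against_hand_formula(self, A, B):
        A, B = [float(x) for x in A], [float(x) for x in B]
        ssA = sum((x - sum(A) / len(A)) ** 2 for x in A)
        ssB = sum((x - sum(B) / len(B)) ** 2 for x in B)
        if ssA + ssB == 0:
            with pytest.raises(DegenerateDataError):
                cohens_d_unbiased(A, B)
            return
        eff = cohens_d_unbiased(A, B)
        assert eff.d_unb == pytest.approx(d_unb_by_hand(A, B), rel=1e-12, abs=1e-12)
        assert eff.category == classify_effect(eff.d_unb)


class TestEffectClassification:
    @pytest.mark.parametrize(
        "d,category",
        [(0.1, "negligible"), (0.2, "negligible"), (0.21, "small"), (0.5, "small"),
         (0.6, "medium"), (0.8, "medium"), (0.85, "large"), (-0.85, "large")],
    )
    def test_printed_thresholds_exclusive(self, d, category):
        assert classify_effect(d) == category

    def test_monotone_in_magnitude(self):
        order = ["negligible", "small", "medium", "large"]
        ranks = [order.index(classify_effect(d)) for d in np.linspace(0, 2, 100)]
        assert np.all(np.diff(ranks) >= 0)


class TestSignificanceDecision:
    def test_two_stage_criterion(self):
        eff_small = cohens_d_unbiased([0.0, 1.0, 2.3], [-0.3, 0.5, 1.0])
        assert abs(eff_small.d_unb) > 0.2
        assert significance_decision(0.04, eff_small).flagged
        assert not significance_decision(0.2, eff_small).flagged

    def test_large_p_never_flagged_even_for_huge_effect(self):
        eff = cohens_d_unbiased([10.0, 11.0], [0.0, 1.0])
        assert abs(eff.d_unb) > 0.8
        assert not significance_decision(0.051, eff).flagged

    def test_small_effect_never_flagged_even_for_tiny_p(self):
        eff = cohens_d_unbiased([0.0, 1.0, 2.0], [0.1, 1.1, 2.1])
        assert abs(eff.d_unb) < 0.2
        assert not significance_decision(0.001, eff).flagged


class TestCorrelations:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_samples_near_zero(self, rng):
        r = pearson_correlation(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(r) < 0.05

    def test_toy_hand_value(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_variable_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestReplicateCorrelationComparison:
    def test_beta_is_difference_of_means(self):
        beta, _, _ = compare_replicate_correlations([0.718] * 3, [0.464] * 3)
        assert beta == pytest.approx(0.254)

    def test_identical_lists_give_zero_difference(self):
        beta, t, p = compare_replicate_correlations([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert beta == 0.0 and t == 0.0 and p == 1.0

    def test_matches_hand_computed_t(self):
        rA, rB = [0.7, 0.72, 0.71], [0.46, 0.47, 0.46]
        beta, t, p = compare_replicate_correlations(rA, rB)
        # pooled two-sample t computed directly
        mA, mB = np.mean(rA), np.mean(rB)
        sp2 = (np.sum((rA - mA) ** 2) + np.sum((rB - mB) ** 2)) / 4
        t_hand = (mA - mB) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert beta == pytest.approx(mA - mB)
        assert t == pytest.approx(t_hand, rel=1e-10)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df=4), rel=1e-10)


class TestNullCalibration:
    def test_flag_rate_bounded_under_null(self):
        """Identical generating distributions: the p<=0.05 & d>0.2 scheme flags
        no more than ~5% of comparisons (the d gate can only reduce the rate)."""
        rng = np.random.default_rng(SEED)
        n_sims, flags = 400, 0
        for _ in range(n_sims):
            cmp_ = compare_groups(rng.normal(size=3), rng.normal(size=3))
            flags += cmp_.flagged
        rate = flags / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert rate <= 0.05 + 3 * se
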