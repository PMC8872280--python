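"""Validity statistics: ROC/Youden, rank-sum, partial-F ANCOVA, Bartlett."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from tempodisc.validity import (
    bartlett_test,
    partial_f_ancova,
    roc_curve,
    wilcoxon_ranksum,
    youden_optimal,
)


def mann_whitney_auc(pos, neg, direction="higher_is_positive"):
    """Brute-force pair-counting oracle: P(pos beats neg), ties half."""
    sign = 1.0 if direction == "higher_is_positive" else -1.0
    wins = 0.0
    for p in pos:
        for n in neg:
            if sign * p > sign * n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([3, 4, 5], [0, 1, 2], "higher_is_positive")
        assert roc.auc_roc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)

    def test_identical_groups_chance_level(self):
        roc = roc_curve([1, 2, 3], [1, 2, 3], "higher_is_positive")
        assert roc.auc_roc == pytest.approx(0.5)
        assert roc.youden_j == pytest.approx(0.0)

    def test_auc_equals_pair_counting_oracle(self, rng):
        for _ in range(60):
            n1, n2 = rng.integers(2, 9, 2)
            pos = rng.integers(0, 6, n1).astype(float)  # integer scores force ties
            neg = rng.integers(0, 6, n2).astype(float)
            direction = "higher_is_positive" if rng.random() < 0.5 else "lower_is_positive"
            roc = roc_curve(pos, neg, direction)
            assert roc.auc_roc == pytest.approx(
                mann_whitney_auc(pos, neg, direction), abs=1e-12
            )

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(1.0, 1.0, 40)
        neg = rng.normal(0.0, 1.0, 60)
        roc = roc_curve(pos, neg, "higher_is_positive")
        y = np.r_[np.ones(40), np.zeros(60)]
        assert roc.auc_roc == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)

    def test_reversing_direction_complements_auc(self, rng):
        pos = rng.normal(1.0, 1.0, 25)
        neg = rng.normal(0.0, 1.0, 30)
        a1 = roc_curve(pos, neg, "higher_is_positive").auc_roc
        a2 = roc_curve(pos, neg, "lower_is_positive").auc_roc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_tpr_fpr_jointly_monotone(self, rng):
        roc = roc_curve(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_curve([], [1.0, 2.0])


class TestYouden:
    def test_toy_argmax_by_enumeration(self):
        pos = [2.0, 3.0, 5.0, 6.0]
        neg = [1.0, 2.0, 4.0, 4.5]
        roc = roc_curve(pos, neg, "higher_is_positive")
        j, cutoff = youden_optimal(roc)
        # exhaustive enumeration over every candidate cutoff
        best = -1.0
        for c in sorted(set(pos + neg)):
            tpr = sum(p >= c for p in pos) / len(pos)
            fpr = sum(n >= c for n in neg) / len(neg)
            best = max(best, tpr - fpr)
        assert j == pytest.approx(best)
        assert cutoff in set(pos + neg)

    def test_tie_broken_toward_lower_fpr(self):
        # two cutoffs reach J = 0.5; the one with smaller FPR must win
        pos = [1.0, 3.0]
        neg = [0.0, 2.0]
        roc = roc_curve(pos, neg, "higher_is_positive")
        j, cutoff = youden_optimal(roc)
        assert j == pytest.approx(0.5)
        assert cutoff == 3.0  # tpr .5/fpr 0 beats tpr 1/fpr .5


class TestWilcoxonRankSum:
    def test_complete_separation_maximal_statistic(self):
        res = wilcoxon_ranksum([10, 11, 12], [1, 2, 3, 4])
        assert res.statistic == 12  # n1 * n2

    def test_identical_samples_non_significant(self):
        res = wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value >= 0.9

    def test_close_to_exact_permutation_p(self, rng):
        x = [0.3, 1.1, 2.0, 2.5, 4.2]
        y = [0.9, 1.4, 3.1, 3.3, 5.0]
        res = wilcoxon_ranksum(x, y)
        pooled = np.array(x + y)
        obs = res.statistic
        count = 0
        total = 0
        for idx in itertools.combinations(range(10), 5):
            sel = np.zeros(10, bool)
            sel[list(idx)] = True
            ranks = stats.rankdata(pooled)
            u = ranks[sel].sum() - 15.0
            if abs(u - 12.5) >= abs(obs - 12.5) - 1e-9:
                count += 1
            total += 1
        exact_p = count / total
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        res = wilcoxon_ranksum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.8, 1, 20)
        r1 = wilcoxon_ranksum(x, y)
        r2 = wilcoxon_ranksum(np.exp(x), np.exp(y))  # strictly increasing map
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            wilcoxon_ranksum([1.0, 1.0], [1.0, 1.0, 1.0])


class TestPartialFAncova:
    def test_two_group_no_covariate_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.7, 1, 25)
        out = partial_f_ancova(np.r_[x, y], ["a"] * 20 + ["b"] * 25)
        t = stats.ttest_ind(x, y, equal_var=True)
        assert out["group"].statistic == pytest.approx(t.statistic ** 2, abs=1e-8)
        assert out["group"].p_value == pytest.approx(t.pvalue, abs=1e-10)

    def test_eta_squared_identity(self, rng):
        n = 60
        y = rng.normal(0, 1, n)
        group = rng.choice(["a", "b", "c"], n)
        cov = {"sex": rng.choice(["F", "M"], n), "age": rng.normal(50, 10, n)}
        for res in partial_f_ancova(y, group, cov).values():
            df1, df2 = res.df
            expected = (res.statistic * df1) / (res.statistic * df1 + df2)
            assert res.effect_size == pytest.approx(expected, abs=1e-10)

    def test_matches_statsmodels_type2(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n = 80
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, n),
                "group": rng.choice(["ctl", "pat"], n),
                "sex": rng.choice(["F", "M"], n),
                "edu": rng.choice(["1", "2", "3"], n),
            }
        )
        df["y"] += (df["group"] == "pat") * 0.8
        ours = partial_f_ancova(df["y"], df["group"],
                                {"sex": df["sex"], "edu": df["edu"]})
        fit = ols("y ~ C(group) + C(sex) + C(edu)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for term, row in [("group", "C(group)"), ("sex", "C(sex)"), ("edu", "C(edu)")]:
            assert ours[term].statistic == pytest.approx(ref.loc[row, "F"], rel=1e-8)
            assert ours[term].p_value == pytest.approx(ref.loc[row, "PR(>F)"], rel=1e-6)

    def test_strong_shift_detected(self, rng):
        # groups separated by 3 residual SDs at n = 50/50
        y = np.r_[rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
        out = partial_f_ancova(y, ["a"] * 50 + ["b"] * 50)
        assert out["group"].p_value < 0.001

    def test_aliased_columns_named(self, rng):
        n = 30
        group = rng.choice(["a", "b"], n)
        cov = {"dup": (np.asarray(group) == "b").astype(float)}  # aliases the dummy
        with pytest.raises(ValueError, match="rank deficient"):
            partial_f_ancova(rng.normal(0, 1, n), group, cov)


class TestBartlett:
    def test_identical_groups_statistic_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = bartlett_test([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_group_case(self):
        # n = (5, 5), variance ratio 16: closed-form K^2
        g1 = [0.0, 1.0, 2.0, 3.0, 4.0]          # var 2.5
        g2 = [0.0, 4.0, 8.0, 12.0, 16.0]        # var 40
        ni = np.array([5.0, 5.0])
        vi = np.array([2.5, 40.0])
        n, g = 10.0, 2.0
        sp2 = ((ni - 1) * vi).sum() / (n - g)
        k2 = (n - g) * math.log(sp2) - ((ni - 1) * np.log(vi)).sum()
        k2 /= 1.0 + ((1.0 / (ni - 1)).sum() - 1.0 / (n - g)) / (3.0 * (g - 1))
        res = bartlett_test([g1, g2])
        assert res.statistic == pytest.approx(k2, abs=1e-6)

    def test_matches_scipy_reference(self, rng):
        groups = [rng.normal(0, s, 20) for s in (1.0, 1.5, 2.0)]
        res = bartlett_test(groups)
        ref = stats.bartlett(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            bartlett_test([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            bartlett_test([[1.0, 2.0]])
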