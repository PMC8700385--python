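"""Group comparisons, correlations, ROC, confusion metrics and odds ratios."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivimfusion.stats import (
    DiagnosticTable,
    age_adjusted_or,
    confusion_metrics,
    mann_whitney,
    paired_test,
    roc_analysis,
    spearman_vs_age,
)


class TestMannWhitney:
    def test_exact_enumeration_fully_separated(self):
        """A={1,2,3} below B={4,5,6}: U=0 and the exact two-sided p is
        2/20 = 0.1 over the 20 equally likely group assignments."""
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        r = mann_whitney([2, 2, 2], [2, 2, 2])
        assert r.p_value == 1.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(50, 1, 20)
        assert mann_whitney(a, b).p_value < 1e-5

    def test_exact_matches_independent_enumeration(self):
        """For small samples with ties, p matches a from-scratch
        enumeration over all label assignments."""
        a = [1.0, 3.0, 3.0, 7.0]
        b = [2.0, 3.0, 8.0]
        r = mann_whitney(a, b)
        from scipy.stats import rankdata

        pooled = np.array(a + b)
        ranks = rankdata(pooled)
        n1 = len(a)
        us = []
        for idx in combinations(range(len(pooled)), n1):
            us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        us = np.array(us)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        p = min(1.0, 2 * min((us <= u_obs + 1e-12).mean(), (us >= u_obs - 1e-12).mean()))
        assert r.p_value == pytest.approx(p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestPaired:
    def test_identical_pairs_degenerate_p_one(self):
        r = paired_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.degenerate
        assert r.p_value == 1.0

    def test_constant_shift_with_shrinking_jitter(self):
        """p falls toward 0 as the jitter on a constant nonzero difference
        shrinks (closed-form t = mean/SE grows)."""
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 10, 8)
        last_p = 1.0
        for eps in (0.5, 0.05, 0.005):
            jitter = rng.normal(0, eps, 8)
            p = paired_test(base + 1.0 + jitter, base).p_value
            assert p < last_p
            last_p = p
        assert last_p < 1e-10

    def test_lesion_normal_effect_size_power(self):
        """True D shift -0.29 (report units) with paired SD 0.15 at n=16:
        significant in >= 80% of 200 replicates."""
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            normal = rng.normal(0.80, 0.10, 16)
            lesion = normal - 0.29 + rng.normal(0, 0.15, 16)
            if paired_test(lesion, normal).p_value < 0.05:
                hits += 1
        assert hits >= 160

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1, 2, 3], [1, 2])

    def test_wilcoxon_companion_reported(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 12)
        r = paired_test(a + 1 + rng.normal(0, 0.3, 12), a)
        assert "wilcoxon_p" in r.companion


class TestSpearman:
    def test_monotone_rho_one(self):
        ages = np.array([30, 40, 50, 60, 70.0])
        assert spearman_vs_age(ages**2, ages).statistic == pytest.approx(1.0, abs=1e-12)

    def test_reversal_flips_sign(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 80, 15)
        vals = rng.normal(0, 1, 15)
        r1 = spearman_vs_age(vals, ages)
        r2 = spearman_vs_age(-vals, ages)
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_null_calibration(self):
        """Values independent of age: mean rho over replicates near 0."""
        rng = np.random.default_rng(5)
        rhos = []
        for _ in range(1000):
            ages = rng.uniform(24, 84, 38)
            vals = rng.normal(0, 1, 38)
            rhos.append(spearman_vs_age(vals, ages).statistic)
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_values_flagged(self):
        r = spearman_vs_age([1, 1, 1, 1, 1], [10, 20, 30, 40, 50])
        assert r.degenerate
        assert np.isnan(r.statistic)


def auc_by_pair_counting(pos, neg, lower_is_positive=False):
    """Brute-force AUC: fraction of (pos, neg) pairs ranked correctly,
    ties counting one half."""
    s = -1.0 if lower_is_positive else 1.0
    wins = ties = 0
    for p, n in product(pos, neg):
        if s * p > s * n:
            wins += 1
        elif p == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.auc == 1.0
        assert r.orientation == "lower_is_positive"
        assert 3.0 < r.cutoff < 10.0
        cm = confusion_metrics(r.table)
        assert cm["sensitivity"] == 100.0 and cm["specificity"] == 100.0

    def test_auc_equals_u_statistic_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            pos = rng.normal(1, 1, rng.integers(5, 20))
            neg = rng.normal(0, 1, rng.integers(5, 20))
            r = roc_analysis(pos, neg, orientation="higher_is_positive")
            assert r.auc == pytest.approx(auc_by_pair_counting(pos, neg), abs=1e-12)

    def test_interleaved_classes_pair_counting_oracle(self):
        """{1,3,5} lesions vs {2,4,6} normals: pair enumeration gives 3/9
        for higher-is-positive, hence 6/9 after orientation flip."""
        lesion, normal = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        assert auc_by_pair_counting(lesion, normal) == pytest.approx(3 / 9)
        r = roc_analysis(lesion, normal)  # auto-orientation keeps AUC >= 0.5
        assert r.orientation == "lower_is_positive"
        assert r.auc == pytest.approx(6 / 9)

    def test_ties_counted_half(self):
        r = roc_analysis([1.0, 2.0], [2.0, 3.0], orientation="lower_is_positive")
        assert r.auc == pytest.approx(auc_by_pair_counting([1, 2], [2, 3], True))

    def test_degenerate_constant_classes(self):
        r = roc_analysis([5.0, 5.0], [5.0, 5.0])
        assert r.auc == 0.5
        assert r.degenerate

    def test_cutoff_is_midpoint_and_maximizes_youden(self):
        r = roc_analysis([1.0, 2.0, 3.0], [2.5, 4.0, 5.0])
        assert r.cutoff == pytest.approx(2.25)  # midpoint of 2.0 and 2.5
        assert r.youden_j == pytest.approx(2 / 3 + 1.0 - 1.0)

    @given(
        st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)), min_size=3, max_size=15),
        st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)), min_size=3, max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, pos, neg):
        """AUC is invariant under a strictly increasing transform."""
        pos, neg = np.asarray(pos), np.asarray(neg)
        r1 = roc_analysis(pos, neg, orientation="higher_is_positive")
        r2 = roc_analysis(np.exp(pos / 25), np.exp(neg / 25),
                          orientation="higher_is_positive")
        assert r1.auc == pytest.approx(r2.auc, abs=1e-9)

    def test_delong_ci_contains_auc_and_shrinks(self):
        rng = np.random.default_rng(7)
        pos, neg = rng.normal(1, 1, 200), rng.normal(0, 1, 200)
        r_big = roc_analysis(pos, neg, orientation="higher_is_positive")
        r_small = roc_analysis(pos[:20], neg[:20], orientation="higher_is_positive")
        assert r_big.ci_low <= r_big.auc <= r_big.ci_high
        assert (r_big.ci_high - r_big.ci_low) < (r_small.ci_high - r_small.ci_low)


class TestConfusion:
    @pytest.mark.parametrize(
        "tp,fn,fp,tn,expect",
        [
            (14, 2, 1, 15, {"sensitivity": 87.5, "specificity": 93.75,
                            "ppv": 93.33, "npv": 88.24, "accuracy": 90.625}),
            (10, 6, 0, 16, {"sensitivity": 62.5, "specificity": 100.0,
                            "ppv": 100.0, "npv": 72.73, "accuracy": 81.25}),
            (12, 4, 5, 11, {"sensitivity": 75.0, "specificity": 68.75,
                            "ppv": 70.59, "npv": 73.33, "accuracy": 71.875}),
        ],
    )
    def test_metric_values(self, tp, fn, fp, tn, expect):
        m = confusion_metrics(DiagnosticTable(tp=tp, fn=fn, fp=fp, tn=tn))
        for k, v in expect.items():
            assert m[k] == pytest.approx(v, abs=0.005)

    def test_from_rates_reconstruction(self):
        t = DiagnosticTable.from_rates(87.5, 93.8, 16, 16)
        assert (t.tp, t.fn, t.fp, t.tn) == (14, 2, 1, 15)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, deadline=None)
    def test_identities(self, tp, fn, fp, tn):
        """accuracy*total = 100*(TP+TN) exactly; each rate reproduces its
        defining ratio to machine precision."""
        if tp + fn == 0 or fp + tn == 0:
            with pytest.raises(ValueError):
                confusion_metrics(DiagnosticTable(tp=tp, fn=fn, fp=fp, tn=tn))
            return
        m = confusion_metrics(DiagnosticTable(tp=tp, fn=fn, fp=fp, tn=tn))
        total = tp + fn + fp + tn
        assert m["accuracy"] * total == pytest.approx(100 * (tp + tn), abs=1e-9)
        assert m["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        if tp + fp == 0:
            assert m["ppv"] is None
        else:
            assert m["ppv"] == pytest.approx(100 * tp / (tp + fp))

    def test_ppv_not_available_when_no_calls(self):
        m = confusion_metrics(DiagnosticTable(tp=0, fn=16, fp=0, tn=16))
        assert m["ppv"] is None


class TestAgeAdjustedOR:
    def test_null_calibration(self):
        """Exposure independent of outcome, n=200: median OR near 1."""
        rng = np.random.default_rng(8)
        ors = []
        for _ in range(100):
            y = rng.integers(0, 2, 200)
            x = rng.integers(0, 2, 200).astype(float)
            age = rng.uniform(40, 80, 200)
            r = age_adjusted_or(y, x, age)
            if r.available:
                ors.append(r.odds_ratio)
        assert 0.8 <= np.median(ors) <= 1.25

    def test_complete_separation_not_available(self):
        y = np.array([1] * 8 + [0] * 8)
        x = y.astype(float)  # perfectly separating dichotomy
        age = np.linspace(50, 80, 16)
        r = age_adjusted_or(y, x, age)
        assert not r.available
        assert "separation" in r.reason

    def test_constant_age_equals_crossproduct(self):
        """With constant age the adjusted OR collapses to the 2x2
        cross-product ratio (a*d)/(b*c)."""
        y = np.array([1] * 10 + [0] * 10)
        x = np.array([1] * 7 + [0] * 3 + [1] * 4 + [0] * 6, dtype=float)
        age = np.full(20, 60.0)
        r = age_adjusted_or(y, x, age)
        a = np.sum((y == 1) & (x == 1))
        b = np.sum((y == 1) & (x == 0))
        c = np.sum((y == 0) & (x == 1))
        d = np.sum((y == 0) & (x == 0))
        assert r.available
        assert r.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            age_adjusted_or([1, 0, 1], [1.0, 0, 1], [60, 61, 62])
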