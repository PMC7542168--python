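import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from textrisk.evaluation import (auc_to_cohens_d, cohens_d_from_t,
                                 group_comparisons, repeated_cv, roc_and_auc,
                                 stratified_split, summarize_aucs)
from textrisk.models import ModelConfig


def mann_whitney_auc(scores, labels):
    """Exhaustive pair-counting oracle: (concordant + ties/2) / (n1*n0)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_published_portion_sizes(self):
        labels = np.zeros(1002, dtype=int)
        labels[:361] = 1
        plan = stratified_split(labels, seed=0)
        assert len(plan.train) == 701
        assert len(plan.dev) == 150
        assert len(plan.test) == 151

    @pytest.mark.parametrize("seed", range(20))
    def test_positive_fraction_equal_within_one_user(self, seed):
        labels = np.zeros(1002, dtype=int)
        labels[:361] = 1
        plan = stratified_split(labels, seed=seed)
        fractions = np.array([0.70, 0.15, 0.15])
        for part, frac in zip(plan, fractions):
            expected = 361 * frac
            assert abs(labels[part].sum() - expected) <= 1

    def test_partition_is_exhaustive_and_disjoint(self):
        labels = (np.random.default_rng(0).random(317) < 0.3).astype(int)
        plan = stratified_split(labels, seed=4)
        combined = np.concatenate([plan.train, plan.dev, plan.test])
        assert len(combined) == 317
        assert len(np.unique(combined)) == 317

    def test_all_negative_degenerate(self):
        plan = stratified_split(np.zeros(40, dtype=int), seed=0)
        assert len(plan.train) == 28

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 1]), fractions=(0.5, 0.3, 0.1))


class TestRocAuc:
    def test_perfect_ranking(self):
        roc, auc = roc_and_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                               np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_pure_ties_give_half(self):
        _, auc = roc_and_auc(np.full(10, 0.5),
                             np.array([1, 0] * 5))
        assert auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        roc, _ = roc_and_auc(scores, labels)
        assert roc.tpr[0] == 0 and roc.fpr[0] == 0
        assert roc.tpr[-1] == 1 and roc.fpr[-1] == 1
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(st.data())
    def test_equals_exhaustive_pair_counting(self, data):
        n = data.draw(st.integers(4, 30))
        n_pos = data.draw(st.integers(1, n - 1))
        # coarse score grid to force plenty of ties
        scores = np.array(data.draw(st.lists(
            st.integers(0, 5), min_size=n, max_size=n))) / 5.0
        labels = np.zeros(n, dtype=int)
        labels[:n_pos] = 1
        _, auc = roc_and_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels),
                                    abs=1e-12)


class TestEffectSizes:
    @pytest.mark.parametrize("auc,d", [
        (0.5, 0.0),
        (0.621, 0.436),
        (0.629, 0.466),
        (0.697, 0.729),
        (0.746, 0.936),
    ])
    def test_binormal_conversion_matches_published_values(self, auc, d):
        assert round(auc_to_cohens_d(auc), 3) == d

    def test_round_trip_through_normal_cdf(self):
        for auc in (0.51, 0.621, 0.746, 0.93):
            d = auc_to_cohens_d(auc)
            assert stats.norm.cdf(d / np.sqrt(2)) == pytest.approx(
                auc, abs=1e-12)

    def test_domain_enforced(self):
        for bad in (0.0, 1.0, -0.1, 1.7):
            with pytest.raises(ValueError):
                auc_to_cohens_d(bad)

    def test_two_normal_simulation_oracle(self, rng):
        """Populations separated by d = 1: the empirical AUC transforms
        back to d within 0.03."""
        a = rng.normal(0.0, 1.0, 20000)
        b = rng.normal(1.0, 1.0, 20000)
        scores = np.concatenate([a, b])
        labels = np.concatenate([np.zeros(20000), np.ones(20000)])
        _, auc = roc_and_auc(scores, labels.astype(int))
        assert auc_to_cohens_d(auc) == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("t,df,d", [
        (0.0, 1000, 0.0),
        (3.27, 1000, 0.207),
        (-5.09, 1000, -0.322),
        (-4.26, 998, -0.270),
    ])
    def test_t_conversion_matches_published_values(self, t, df, d):
        assert round(cohens_d_from_t(t, df), 3) == d

    def test_t_conversion_ci_width(self):
        d, (lo, hi) = cohens_d_from_t(3.27, 1000, ci=True)
        assert hi - lo == pytest.approx(2 * 1.96 * 2 / np.sqrt(1000))
        assert lo < d < hi

    def test_t_conversion_rejects_bad_df(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0)


class TestSummaries:
    def test_hand_computed_mean_and_percentiles(self):
        aucs = np.array([0.6, 0.62, 0.64, 0.66, 0.68])
        s = summarize_aucs(aucs)
        assert s["mean_auc"] == pytest.approx(0.64)
        assert s["ci_low"] == pytest.approx(np.percentile(aucs, 2.5))
        assert s["ci_high"] == pytest.approx(np.percentile(aucs, 97.5))

    def test_zero_variance_ci_collapses(self):
        s = summarize_aucs(np.full(5, 0.7))
        assert s["ci_low"] == s["ci_high"] == pytest.approx(0.7)

    def test_chance_level_maps_to_zero_effect(self):
        s = summarize_aucs(np.full(3, 0.5))
        assert s["cohens_d"] == 0.0


class TestRepeatedCv:
    def test_bookkeeping_and_paired_difference(self, oracle_cohort):
        from textrisk.embedding import apply_inclusion_filters
        filtered, _ = apply_inclusion_filters(oracle_cohort)
        configs = [ModelConfig(variant=v, input_dim=32, max_epochs=4,
                               patience=4, seed=1) for v in ("stm", "mtm")]
        report = repeated_cv(filtered, configs, repeats=2, seed=3)
        assert len(report.per_repeat) == 4   # 2 repeats x 2 variants
        assert ("stm", "general") in report.summary
        assert ("mtm_minus_stm", "general") in report.paired
        diffs = report.paired[("mtm_minus_stm", "general")]["differences"]
        assert len(diffs) == 2

    def test_rejects_single_repeat(self, oracle_cohort):
        with pytest.raises(ValueError):
            repeated_cv(oracle_cohort, [], repeats=1)


class TestGroupComparisons:
    def test_identical_groups_null(self):
        class U:
            def __init__(self, risk, bump):
                self.post_count = 10 + bump
                self.age = 30.0 + bump
                self.income = 50000.0 + bump
                self.gender = "male" if bump % 2 else "female"
                self.general_risk = risk

        class C:
            users = [U(r, b) for r in (True, False) for b in range(8)]
            general_risk = np.array([u.general_risk for u in users])

        comps = {c.variable: c for c in group_comparisons(C())}
        for var in ("post_count", "age", "income"):
            assert comps[var].statistic == pytest.approx(0.0)
            assert comps[var].cohens_d == pytest.approx(0.0)
            assert comps[var].df == 14

    def test_hand_computed_pooled_t(self):
        class U:
            _count = iter(range(100))

            def __init__(self, risk, age):
                i = next(U._count)
                self.post_count = 10 + i
                self.age = age
                self.income = 40000.0 + 1000.0 * i
                self.gender = "male" if i % 2 else "female"
                self.general_risk = risk

        class C:
            users = [U(False, 30.0), U(False, 34.0), U(False, 32.0),
                     U(True, 25.0), U(True, 27.0), U(True, 29.0)]
            general_risk = np.array([False, False, False, True, True, True])

        comps = {c.variable: c for c in group_comparisons(C())}
        # pooled sd: both groups have variance 4 -> sp=2; se = 2*sqrt(2/3)
        t_expected = (27.0 - 32.0) / (2 * np.sqrt(2 / 3))
        assert comps["age"].statistic == pytest.approx(t_expected)
        assert comps["age"].df == 4
        assert comps["age"].cohens_d == pytest.approx(
            2 * t_expected / 2.0)

    def test_synthetic_cohort_effect_directions(self, calibration):
        from textrisk.cohort import generate_cohort
        cohort = generate_cohort(calibration, 1000, seed=17, mode="oracle",
                                 embed_dim=8)
        comps = {c.variable: c for c in group_comparisons(cohort)}
        assert comps["age"].statistic < 0          # risk group younger
        assert comps["income"].statistic < 0       # and poorer
        assert comps["post_count"].statistic > 0   # but posts more
        assert comps["gender_male"].kind == "chi2"
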