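"""Validation metrics against hand-computed tables and independent oracles."""

import numpy as np
import pytest

from ktsp import (
    DegenerateInputError,
    SurvivalRecords,
    auc_bootstrap_ci,
    confusion_metrics,
    generate_survival,
    kaplan_meier,
    logrank_test,
    resubstitution_auc,
    roc_and_auc,
)
from ktsp.core import GOOD, POOR


def _labels(n_poor, n_good):
    return np.array([POOR] * n_poor + [GOOD] * n_good, dtype=object)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        t = _labels(3, 3)
        assert confusion_metrics(t, t) == (1.0, 1.0, 1.0)

    def test_all_called_poor(self):
        t = _labels(3, 5)
        pred = np.array([POOR] * 8, dtype=object)
        sens, spec, acc = confusion_metrics(pred, t)
        assert (sens, spec) == (1.0, 0.0)
        assert acc == pytest.approx(3 / 8)

    def test_printed_two_by_two_table(self):
        # TP=9, FN=1, TN=5, FP=5 -> 0.9 / 0.5 / 0.7
        truth = _labels(10, 10)
        pred = np.array(
            [POOR] * 9 + [GOOD] + [POOR] * 5 + [GOOD] * 5, dtype=object
        )
        sens, spec, acc = confusion_metrics(pred, truth)
        assert (sens, spec, acc) == (0.9, 0.5, 0.7)

    def test_accuracy_is_class_weighted_mean_of_sens_spec(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n_poor = int(rng.integers(1, 20))
            n_good = int(rng.integers(1, 20))
            truth = _labels(n_poor, n_good)
            pred = np.where(rng.random(n_poor + n_good) < 0.5, POOR, GOOD).astype(object)
            sens, spec, acc = confusion_metrics(pred, truth)
            n = n_poor + n_good
            assert acc == pytest.approx((sens * n_poor + spec * n_good) / n)


class TestRocAndAuc:
    def test_perfect_separation(self):
        _, auc = roc_and_auc(np.array([3, 3, 1, 0]), _labels(2, 2))
        assert auc == 1.0

    def test_roc_endpoints_and_monotonicity(self):
        scores = np.array([4, 2, 1, 3, 0, 2])
        pts, _ = roc_and_auc(scores, _labels(3, 3))
        assert (pts[0][1], pts[0][2]) == (0.0, 0.0)
        assert (pts[-1][1], pts[-1][2]) == (1.0, 1.0)
        tpr = [p[1] for p in pts]
        fpr = [p[2] for p in pts]
        assert tpr == sorted(tpr) and fpr == sorted(fpr)

    def test_label_permutation_gives_null_auc(self):
        rng = np.random.default_rng(22)
        aucs = []
        for _ in range(200):
            scores = rng.integers(0, 9, size=40)
            labels = _labels(20, 20)
            rng.shuffle(labels)
            _, auc = roc_and_auc(scores, labels)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_trapezoid_equals_mann_whitney(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 10, size=n)
            labels = np.where(rng.random(n) < 0.4, POOR, GOOD).astype(object)
            if len(set(labels)) < 2:
                continue
            _, auc = roc_and_auc(scores, labels)
            assert auc == pytest.approx(
                resubstitution_auc(scores, labels), abs=1e-12
            )


class TestAucBootstrapCi:
    def test_deterministic_given_seed(self):
        scores = np.array([5, 4, 4, 3, 2, 2, 1, 0])
        labels = _labels(4, 4)
        a = auc_bootstrap_ci(scores, labels, n_boot=500, seed=99)
        b = auc_bootstrap_ci(scores, labels, n_boot=500, seed=99)
        assert a == b

    def test_perfect_separation_collapses_to_one(self):
        scores = np.concatenate([np.full(60, 5), np.full(60, 1)])
        lo, hi = auc_bootstrap_ci(scores, _labels(60, 60), n_boot=200, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc_bootstrap_ci(np.array([1, 2, 3]), _labels(1, 2), seed=0)

    def test_matches_independent_resampling_loop(self):
        scores = np.array([4, 3, 3, 2, 1, 2, 0, 1, 2, 0])
        labels = _labels(5, 5)
        got = auc_bootstrap_ci(scores, labels, level=0.9, n_boot=1000, seed=7)
        # oracle: re-implemented stratified percentile bootstrap, same stream
        rng = np.random.default_rng(7)
        pos = np.flatnonzero(labels == POOR)
        neg = np.flatnonzero(labels == GOOD)
        stats = []
        for _ in range(1000):
            p = rng.choice(pos, size=len(pos), replace=True)
            g = rng.choice(neg, size=len(neg), replace=True)
            idx = np.concatenate([p, g])
            stats.append(resubstitution_auc(scores[idx], labels[idx]))
        lo, hi = np.quantile(stats, [0.05, 0.95])
        assert got == pytest.approx((lo, hi))


class TestKaplanMeier:
    def test_all_censored_means_flat_one(self):
        rec = SurvivalRecords(np.array([1.0, 2.0, 3.0]), np.zeros(3, dtype=int))
        assert kaplan_meier(rec) == []

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(31)
        times = rng.exponential(10.0, size=50)
        rec = SurvivalRecords(times, np.ones(50, dtype=int))
        for t, s in kaplan_meier(rec):
            assert s == pytest.approx(1.0 - (times <= t).mean())

    def test_hand_computed_product_limit_with_censoring(self):
        # times 1, 2, 3+, 4, 5, 6 (3 censored): steps at 1, 2, 4, 5, 6
        rec = SurvivalRecords(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([1, 1, 0, 1, 1, 1]),
        )
        expected = [
            (1.0, 5 / 6),
            (2.0, 5 / 6 * 4 / 5),
            (4.0, 5 / 6 * 4 / 5 * 2 / 3),
            (5.0, 5 / 6 * 4 / 5 * 2 / 3 * 1 / 2),
            (6.0, 0.0),
        ]
        got = kaplan_meier(rec)
        assert [t for t, _ in got] == [t for t, _ in expected]
        for (_, s), (_, e) in zip(got, expected):
            assert s == pytest.approx(e)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(32)
        times = rng.exponential(10.0, size=80)
        events = (rng.random(80) < 0.7).astype(int)
        rec = SurvivalRecords(times, events)
        km = KaplanMeierFitter().fit(times, events)
        for t, s in kaplan_meier(rec):
            assert s == pytest.approx(
                float(km.survival_function_at_times(t).iloc[0])
            )


class TestLogrank:
    def test_identical_groups_score_zero(self):
        times = np.array([2.0, 4.0, 6.0, 8.0] * 2)
        events = np.array([1, 1, 0, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        stat, p = logrank_test(SurvivalRecords(times, events), groups)
        assert stat == 0.0
        assert p == 1.0

    def test_single_group_is_degenerate(self):
        rec = SurvivalRecords(np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(DegenerateInputError):
            logrank_test(rec, np.array(["a", "a"], dtype=object))

    def test_textbook_toy_against_hand_tables(self):
        # group a: 3.5+, 5, 8, 10; group b: 1, 2, 4+, 6
        times = np.array([3.5, 5.0, 8.0, 10.0, 1.0, 2.0, 4.0, 6.0])
        events = np.array([0, 1, 1, 1, 1, 1, 0, 1])
        groups = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        # hand-computed hypergeometric terms for group a at event times
        # 1, 2, 5, 6, 8, 10 with risk sets (n, n_a) =
        # (8,4), (7,4), (4,3), (3,2), (2,2), (1,1):
        o_minus_e = (0 - 4 / 8) + (0 - 4 / 7) + (1 - 3 / 4) + (0 - 2 / 3) \
            + (1 - 1) + (1 - 1)
        var = (4 * 4) / 8**2 + (4 * 3) / 7**2 + (3 * 1) / 4**2 + (2 * 1) / 3**2
        expected = o_minus_e**2 / var
        stat, _ = logrank_test(SurvivalRecords(times, events), groups)
        assert stat == pytest.approx(expected)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(33)
        times = rng.exponential(10.0, size=60)
        events = (rng.random(60) < 0.8).astype(int)
        groups = np.where(rng.random(60) < 0.5, "a", "b").astype(object)
        stat, p = logrank_test(SurvivalRecords(times, events), groups)
        res = ll_logrank(
            times[groups == "a"], times[groups == "b"],
            events[groups == "a"], events[groups == "b"],
        )
        assert stat == pytest.approx(res.test_statistic)
        assert p == pytest.approx(res.p_value)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(34)
        pvals = []
        for _ in range(200):
            labels = np.array([POOR] * 25 + [GOOD] * 25, dtype=object)
            rec = generate_survival(labels, hazard_ratio=1.0,
                                    seed=int(rng.integers(2**31)))
            groups = labels
            pvals.append(logrank_test(rec, groups)[1])
        # at the null about 5% of p-values fall below 0.05
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= frac <= 0.12


class TestPowerOfPlantedHazard:
    def test_hazard_ratio_three_is_detected(self):
        rng = np.random.default_rng(35)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            labels = np.array([POOR] * 100 + [GOOD] * 100, dtype=object)
            rec = generate_survival(labels, hazard_ratio=3.0,
                                    seed=int(rng.integers(2**31)))
            if logrank_test(rec, labels)[1] < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.95
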