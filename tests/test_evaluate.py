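"""Classification metrics, repeated CV, AUC intervals, paired Wilcoxon tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from aneucloud.evaluate import (
    CVReport,
    ModelSpec,
    auc_interval,
    compare_groups,
    compute_metrics,
    null_calibration,
    run_experiment,
    run_repeated_cv,
)
from aneucloud.features import FeatureTable
from aneucloud.types import ContractError


def _auc_bruteforce(labels, scores):
    """Pair-counting AUC oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _wilcoxon_exact_oracle(diffs):
    """Two-sided exact signed-rank p by full 2^n sign enumeration."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.array(stats)
    mean = stats.mean()
    tail = min(np.mean(stats <= w_obs), np.mean(stats >= w_obs))
    # two-sided: double the smaller tail (capped at 1)
    return min(1.0, 2 * tail), w_obs, mean


class TestMetrics:
    def test_confusion_matrix_definitions(self):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2,  # TP=3, FN=1
                           0.6, 0.1, 0.1, 0.1, 0.2, 0.2, 0.3, 0.3, 0.4, 0.4])
        m = compute_metrics(scores, labels)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["accuracy"] == pytest.approx(12 / 14)

    def test_all_tied_scores_auc_half(self):
        labels = np.array([1, 0, 1, 0, 0])
        m = compute_metrics(np.full(5, 0.7), labels)
        assert m["auc"] == pytest.approx(0.5)

    def test_perfect_ranking(self):
        m = compute_metrics(np.array([0.9, 0.8, 0.1, 0.2]),
                            np.array([1, 1, 0, 0]))
        assert m["auc"] == 1.0

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            m = compute_metrics(scores, labels)
            assert m["auc"] == pytest.approx(_auc_bruteforce(labels, scores))

    def test_auc_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        a = compute_metrics(scores, labels)["auc"]
        b = compute_metrics(np.exp(3 * scores), labels)["auc"]
        assert a == pytest.approx(b)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        m = compute_metrics(scores, labels)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / labels.size)


class TestAUCInterval:
    def test_degenerate_zero_width(self):
        mean, lo, hi = auc_interval(np.full(8, 0.9))
        assert mean == lo == hi == pytest.approx(0.9)

    def test_two_value_hand_computation(self):
        mean, lo, hi = auc_interval(np.array([0.9, 1.0]))
        half = 1.96 * np.std([0.9, 1.0], ddof=1) / np.sqrt(2)
        assert mean == pytest.approx(0.95)
        assert hi - mean == pytest.approx(half)

    def test_contains_mean(self):
        aucs = np.random.default_rng(0).uniform(0.6, 0.9, size=12)
        mean, lo, hi = auc_interval(aucs)
        assert lo <= mean <= hi


def _report(values, seed=0):
    df = pd.DataFrame({"repetition": np.arange(len(values)),
                       "accuracy": values, "auc": values,
                       "sensitivity": values, "specificity": values})
    return CVReport("M", "?", df, n_repeats=len(values), k_folds=10, seed=seed)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        a = _report(np.full(8, 0.8))
        res = compare_groups(a, _report(np.full(8, 0.8)))
        assert res.degenerate and res.p_value == 1.0

    def test_all_positive_n6_exact(self):
        a = _report(np.array([0.5, 0.52, 0.55, 0.53, 0.51, 0.56]))
        b = _report(a.per_repetition["auc"].to_numpy() + 0.05)
        res = compare_groups(a, b)
        assert res.p_value == pytest.approx(1 / 32)
        assert res.direction == "B>A"

    def test_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(1)
        a = _report(rng.uniform(0.5, 0.7, 9))
        b = _report(a.per_repetition["auc"].to_numpy()
                    + rng.uniform(0.01, 0.1, 9))
        r1 = compare_groups(a, b)
        r2 = compare_groups(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert {r1.direction, r2.direction} == {"B>A", "A>B"}

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        base = rng.uniform(0.4, 0.9, size=n)
        diffs = rng.uniform(-0.1, 0.1, size=n)
        diffs[diffs == 0] = 0.01
        res = compare_groups(_report(base), _report(base + diffs))
        p_oracle, _, _ = _wilcoxon_exact_oracle(diffs)
        assert res.p_value == pytest.approx(p_oracle)

    def test_unequal_repeats_rejected(self):
        with pytest.raises(ContractError):
            compare_groups(_report(np.ones(4) * 0.5), _report(np.ones(5) * 0.5))


def _separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = y[:, None] * 10.0 + rng.normal(scale=0.1, size=(n, 4))
    df = pd.DataFrame(x, columns=list("abcd"),
                      index=[f"S{i}" for i in range(n)])
    return FeatureTable(df, y, group_tag="A")


class TestRepeatedCV:
    def test_fold_record_counts(self):
        table = _separable_table()
        rep = run_repeated_cv(table, ModelSpec.default("RF"), n_repeats=3, k=5)
        assert len(rep.per_repetition) == 3
        assert rep.k_folds == 5

    def test_separable_clusters_are_perfect(self):
        table = _separable_table()
        for name in ("RF", "KNN", "SVM"):
            rep = run_repeated_cv(table, ModelSpec.default(name),
                                  n_repeats=2, k=5)
            assert np.all(rep.per_repetition["accuracy"] == 1.0)
            assert np.all(rep.per_repetition["auc"] == 1.0)

    def test_k_above_minority_count_rejected(self):
        table = _separable_table(n=12)
        with pytest.raises(ContractError, match="smaller k"):
            run_repeated_cv(table, ModelSpec.default("RF"), n_repeats=1, k=8)

    def test_null_calibration_near_chance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 6)),
                          columns=list("abcdef"),
                          index=[f"S{i}" for i in range(50)])
        table = FeatureTable(df, np.array([0, 1] * 25), group_tag="A")
        null = null_calibration(table, ModelSpec.default("RF"),
                                n_repeats=5, k=5, seed=0)
        assert abs(null["auc"].mean() - 0.5) <= 0.12

    def test_deterministic_reports(self):
        table = _separable_table(seed=3)
        a = run_repeated_cv(table, ModelSpec.default("XGB"), n_repeats=2, k=4,
                            seed=9)
        b = run_repeated_cv(table, ModelSpec.default("XGB"), n_repeats=2, k=4,
                            seed=9)
        pd.testing.assert_frame_equal(a.per_repetition, b.per_repetition)


class TestExperiment:
    def test_ten_row_report(self):
        a = _separable_table(seed=1)
        rng = np.random.default_rng(5)
        noise = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"),
                             index=a.data.index)
        b = FeatureTable(noise, a.labels, group_tag="B")
        report = run_experiment(a, b, n_repeats=2, k=4, seed=0)
        assert len(report.metrics) == 10
        assert set(report.metrics["group"]) == {"A", "B"}
        assert len(report.pairwise) == 5
        assert {"auc", "auc_ci_low", "auc_ci_high", "accuracy",
                "sensitivity", "specificity"} <= set(report.metrics.columns)
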