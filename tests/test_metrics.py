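"""Metric suite vs independent counting / threshold-sweep oracles."""

import numpy as np
import pytest

from ddiconv.metrics import (
    accuracy,
    anova_oneway,
    auc_micro,
    aupr_micro,
    evaluate_fold,
    f1_multiclass,
    onehot,
    paired_t_test,
    precision_at_k,
    render_table,
    EvalReport,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def sweep_auc(y: np.ndarray, s: np.ndarray) -> float:
    """Rank-based ROC AUC with half credit for ties (Mann-Whitney)."""
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def sweep_aupr(y: np.ndarray, s: np.ndarray) -> float:
    """Average precision by explicit descending-threshold sweep."""
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    total_pos = y.sum()
    ap = 0.0
    tp = 0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # process tied scores as one threshold
            j += 1
        block_pos = y[i:j].sum()
        tp += block_pos
        precision = tp / j
        ap += precision * (block_pos / total_pos)
        i = j
    return float(ap)


def confusion_f1(y_true, y_pred, n_classes, averaging):
    tp = np.zeros(n_classes)
    fp = np.zeros(n_classes)
    fn = np.zeros(n_classes)
    for t, p in zip(y_true, y_pred):
        if t == p:
            tp[t] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    if averaging == "micro":
        denom = 2 * tp.sum() + fp.sum() + fn.sum()
        return 2 * tp.sum() / denom if denom else 0.0
    f1 = np.zeros(n_classes)
    for c in range(n_classes):
        denom = 2 * tp[c] + fp[c] + fn[c]
        f1[c] = 2 * tp[c] / denom if denom else 0.0
    return f1.mean()


# ---------------------------------------------------------------------------


class TestAccuracy:
    def test_examples(self):
        assert accuracy([0, 1, 1], [0, 1, 0]) == pytest.approx(2 / 3)
        assert accuracy([2, 2], [2, 2]) == 1.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 5, 200)
        p = rng.integers(0, 5, 200)
        assert accuracy(y, p) == pytest.approx(sum(a == b for a, b in zip(y, p)) / 200)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])


class TestF1:
    def test_perfect_prediction(self):
        assert f1_multiclass([0, 1, 2], [0, 1, 2]) == 1.0
        assert f1_multiclass([1, 1, 1], [1, 1, 1]) == 1.0

    @pytest.mark.parametrize("averaging", ["macro", "micro"])
    def test_random_instances_match_confusion_oracle(self, averaging):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n, e = int(rng.integers(5, 60)), int(rng.integers(2, 6))
            y = rng.integers(0, e, n)
            p = rng.integers(0, e, n)
            assert f1_multiclass(y, p, averaging, n_classes=e) == pytest.approx(
                confusion_f1(y, p, e, averaging), abs=1e-12
            )

    def test_absent_classes_contribute_zero_to_macro(self):
        # classes 2..4 never appear: macro mean over 5 classes
        val = f1_multiclass([0, 1], [0, 1], "macro", n_classes=5)
        assert val == pytest.approx(2 / 5)


class TestRankingMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 1, 2, 1])
        scores = onehot(y, 3).astype(float)
        assert auc_micro(onehot(y, 3), scores) == 1.0
        assert aupr_micro(onehot(y, 3), scores) == 1.0

    def test_random_scores_aupr_near_prevalence(self):
        rng = np.random.default_rng(2)
        e = 5
        y = rng.integers(0, e, 4000)
        scores = rng.random((4000, e))
        assert aupr_micro(onehot(y, e), scores) == pytest.approx(1 / e, abs=0.02)

    def test_match_sweep_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n, e = int(rng.integers(4, 50)), int(rng.integers(2, 6))
            y = rng.integers(0, e, n)
            scores = np.round(rng.random((n, e)), 2)  # coarse grid forces ties
            oh = onehot(y, e)
            assert auc_micro(oh, scores) == pytest.approx(sweep_auc(oh.ravel(), scores.ravel()), abs=1e-9)
            assert aupr_micro(oh, scores) == pytest.approx(sweep_aupr(oh.ravel(), scores.ravel()), abs=1e-9)

    def test_degenerate_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_micro(np.ones((3, 1), dtype=int), np.random.random((3, 1)))


class TestPrecisionAtK:
    def test_all_correct_any_k(self):
        y = np.array([0, 1, 2])
        scores = onehot(y, 3).astype(float) + 0.1
        for k in (1, 2, 3):
            assert precision_at_k(y, scores, k) == 1.0

    def test_k_equals_n_is_accuracy(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 4, 60)
        scores = rng.random((60, 4))
        assert precision_at_k(y, scores, 60) == pytest.approx(accuracy(y, scores.argmax(axis=1)))

    def test_matches_sort_and_count(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 3, n)
            scores = np.round(rng.random((n, 3)), 1)
            k = int(rng.integers(1, n + 1))
            order = sorted(range(n), key=lambda i: (-scores[i].max(), i))
            expected = np.mean([scores[i].argmax() == y[i] for i in order[:k]])
            assert precision_at_k(y, scores, k) == pytest.approx(expected)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            precision_at_k([0], np.ones((1, 2)), 0)


class TestPairedT:
    def test_identical_vectors(self):
        assert paired_t_test([0.8, 0.9, 0.7], [0.8, 0.9, 0.7]) == (0.0, 1.0)

    def test_constant_nonzero_difference(self, caplog):
        with caplog.at_level("WARNING"):
            t, p = paired_t_test([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_closed_form(self):
        a = np.array([0.91, 0.88, 0.93, 0.90, 0.87])
        b = np.array([0.85, 0.86, 0.88, 0.84, 0.86])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(expected_t, abs=1e-9)
        assert 0 < p < 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestAnova:
    def test_identical_groups_f_zero(self):
        f, p = anova_oneway([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert f == 0.0 and p == 1.0

    def test_equal_means_unequal_spread(self):
        g1 = [1.0, 2.0, 3.0]  # mean 2
        g2 = [0.0, 2.0, 4.0]  # mean 2
        f, _ = anova_oneway(g1, g2)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_three_group_sum_of_squares_formula(self):
        groups = [np.array([4.0, 5.0, 6.0]), np.array([6.0, 7.0, 8.0]), np.array([9.0, 10.0, 11.0])]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        expected = (ss_between / 2) / (ss_within / 6)
        f, p = anova_oneway(*groups)
        assert f == pytest.approx(expected, abs=1e-9)
        assert p < 0.05

    def test_group_validation(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0])


class TestReports:
    def test_evaluate_fold_and_table(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 3, 40)
        proba = rng.dirichlet(np.ones(3), size=40)
        row = evaluate_fold(y, proba, 3)
        assert set(row) == {"ACC", "F1", "AUC", "AUPR"}
        assert all(0 <= v <= 1 for v in row.values())
        report = EvalReport(model_label="toy", feature_label="S")
        report.add(row)
        text = render_table([report])
        assert "ACC" in text and "AUPR" in text and "toy" in text
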