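"""Confusion-matrix metrics, benign/malignant split, ROC analysis."""

import numpy as np
import pytest

import liverlesion as ll
from liverlesion.classify import FoldResult
from liverlesion.evaluate import (
    ConfusionMatrix,
    benign_malignant_metrics,
    class_metrics,
    collapse_benign_malignant,
    confusion,
    mcnemar_test,
    roc_benign_malignant,
    roc_from_scores,
    roc_one_vs_rest,
    round_half_up,
)

# the published five-class confusion matrix used as a worked reference input
REFERENCE_MATRIX = np.array(
    [
        [32, 0, 2, 4, 2],
        [0, 27, 2, 0, 0],
        [3, 2, 47, 0, 4],
        [3, 0, 0, 22, 5],
        [3, 0, 6, 13, 36],
    ]
)


def fold(true, probs):
    p = np.asarray(probs, dtype=float)
    return FoldResult(
        lesion_id="L",
        patient_id="P",
        true_label=true,
        predicted_label=ll.CLASS_ORDER[int(np.argmax(p))],
        probabilities=p,
    )


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = list(ll.CLASS_ORDER) * 2
        cm = confusion(labels, labels)
        assert np.array_equal(cm.counts, 2 * np.eye(5, dtype=int))

    def test_reconstructed_label_lists_reproduce_the_matrix(self):
        true, pred = [], []
        for i, t in enumerate(ll.CLASS_ORDER):
            for j, p in enumerate(ll.CLASS_ORDER):
                true += [t] * REFERENCE_MATRIX[i, j]
                pred += [p] * REFERENCE_MATRIX[i, j]
        cm = confusion(true, pred)
        assert np.array_equal(cm.counts, REFERENCE_MATRIX)
        assert np.array_equal(cm.counts.sum(axis=0), REFERENCE_MATRIX.sum(axis=0))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["cyst"], ["fnh"])


class TestClassMetrics:
    @pytest.fixture(scope="class")
    def reference(self):
        return class_metrics(ConfusionMatrix(REFERENCE_MATRIX)).rounded()

    def test_overall_accuracy(self, reference):
        assert reference.overall_accuracy == 0.77

    def test_sensitivity_per_class(self, reference):
        assert [reference.sensitivity[c] for c in ll.CLASS_ORDER] == [
            0.80, 0.93, 0.84, 0.73, 0.62,
        ]

    def test_columnwise_specificity_as_printed(self, reference):
        assert [reference.specificity_as_printed[c] for c in ll.CLASS_ORDER] == [
            0.78, 0.93, 0.82, 0.56, 0.77,
        ]

    def test_one_vs_other_accuracies(self, reference):
        ovo = reference.one_vs_other_accuracy
        assert ovo["adenoma"] == 0.92
        assert ovo["hemangioma"] == 0.91
        assert ovo["hcc"] == 0.88
        assert ovo["metastasis"] == 0.85
        # recomputation gives 209/213 = 0.98 for cysts (a documented
        # discrepancy with the published 0.99)
        assert ovo["cyst"] == 0.98

    def test_identity_matrix_all_ones(self):
        m = class_metrics(ConfusionMatrix(np.eye(5, dtype=int) * 4))
        assert m.overall_accuracy == 1.0
        assert all(v == 1.0 for v in m.sensitivity.values())
        assert all(v == 1.0 for v in m.one_vs_other_accuracy.values())

    def test_matches_brute_force_recount(self, rng):
        true = rng.choice(ll.CLASS_ORDER, size=60)
        pred = rng.choice(ll.CLASS_ORDER, size=60)
        m = class_metrics(confusion(list(true), list(pred)))
        for cls in ll.CLASS_ORDER:
            tp = np.sum((true == cls) & (pred == cls))
            assert m.sensitivity[cls] == pytest.approx(
                tp / max(np.sum(true == cls), 1) if np.sum(true == cls) else 0.0
            )
            denom = np.sum(pred == cls)
            expected = tp / denom if denom else 0.0
            assert m.specificity_as_printed[cls] == pytest.approx(expected)
        assert m.overall_accuracy == pytest.approx(np.mean(true == pred))


class TestBenignMalignant:
    def test_reference_split_metrics(self):
        m = benign_malignant_metrics(ConfusionMatrix(REFERENCE_MATRIX)).rounded()
        assert m.sensitivity["benign"] == 0.92
        assert m.sensitivity["malignant"] == 0.86
        assert m.specificity_as_printed["benign"] == 0.91
        assert m.specificity_as_printed["malignant"] == 0.88
        assert m.overall_accuracy == 0.90

    def test_collapse_conserves_total(self):
        collapsed = collapse_benign_malignant(ConfusionMatrix(REFERENCE_MATRIX))
        assert collapsed.total == REFERENCE_MATRIX.sum()

    def test_diagonal_matrix_collapses_to_ones(self):
        m = benign_malignant_metrics(ConfusionMatrix(np.eye(5, dtype=int) * 3))
        assert m.overall_accuracy == 1.0


class TestRoc:
    def test_separable_scores(self):
        roc = roc_from_scores(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0], bool))
        assert roc.auc == pytest.approx(1.0)
        assert roc.optimal_tpr == 1.0 and roc.optimal_fpr == 0.0

    def test_uninformative_scores(self):
        roc = roc_from_scores(np.full(8, 0.5), np.array([1, 0] * 4, bool))
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_rank_sum_oracle(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = rng.normal(size=n)
            pos = rng.uniform(size=n) > 0.5
            if pos.all() or not pos.any():
                continue
            roc = roc_from_scores(scores, pos)
            u = mannwhitneyu(scores[pos], scores[~pos], alternative="two-sided").statistic
            assert roc.auc == pytest.approx(u / (pos.sum() * (~pos).sum()), abs=1e-9)

    def test_auc_invariant_to_monotone_rescaling(self, rng):
        scores = rng.uniform(size=20)
        pos = rng.uniform(size=20) > 0.4
        pos[0], pos[1] = True, False
        a = roc_from_scores(scores, pos).auc
        b = roc_from_scores(np.exp(3 * scores), pos).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=25)
        pos = rng.uniform(size=25) > 0.5
        pos[0], pos[1] = True, False
        assert roc_from_scores(scores, pos).auc + roc_from_scores(scores, ~pos).auc == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_one_vs_rest_pools_other_classes(self):
        folds = [
            fold("adenoma", [0.8, 0.05, 0.05, 0.05, 0.05]),
            fold("cyst", [0.1, 0.6, 0.1, 0.1, 0.1]),
            fold("hcc", [0.2, 0.1, 0.1, 0.5, 0.1]),
        ]
        roc = roc_one_vs_rest(folds, "adenoma")
        assert roc.auc == pytest.approx(1.0)
        with pytest.raises(ValueError):
            roc_one_vs_rest(folds, "metastasis")  # absent from truth

    def test_benign_malignant_score_is_summed_probability(self):
        folds = [
            fold("cyst", [0.3, 0.5, 0.1, 0.05, 0.05]),
            fold("hcc", [0.05, 0.05, 0.1, 0.5, 0.3]),
        ]
        roc = roc_benign_malignant(folds)
        assert roc.auc == pytest.approx(1.0)
        all_benign = [fold("cyst", [0.2] * 5 if False else [0.2, 0.2, 0.2, 0.2, 0.2])]
        with pytest.raises(ValueError):
            roc_benign_malignant(all_benign)

    def test_youden_cutoff_reported_tpr_fpr_fnr(self):
        scores = np.array([0.9, 0.7, 0.4, 0.2])
        pos = np.array([1, 0, 1, 0], bool)
        roc = roc_from_scores(scores, pos)
        # J = 0.5 at both threshold 0.9 (TPR .5, FPR 0) and 0.4 (TPR 1, FPR .5);
        # the tie resolves to the lowest threshold
        assert roc.optimal_cutoff == pytest.approx(0.4)
        assert roc.optimal_tpr == pytest.approx(1.0)
        assert roc.optimal_fpr == pytest.approx(0.5)
        assert roc.optimal_fnr == pytest.approx(0.0)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected", [(0.775, 0.78), (0.625, 0.63), (0.984, 0.98), (0.995, 1.0)]
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_up(value) == expected


class TestMcNemar:
    def test_identical_classifiers_not_significant(self):
        correct = np.array([1, 0, 1, 1, 0], bool)
        stat, p = mcnemar_test(correct, correct)
        assert stat == 0.0 and p == 1.0

    def test_discordant_pairs_drive_the_statistic(self):
        a = np.array([1] * 20 + [0] * 2, bool)
        b = np.array([0] * 20 + [1] * 2, bool)
        stat, p = mcnemar_test(a, b)
        assert stat == pytest.approx((abs(20 - 2) - 1) ** 2 / 22)
        assert p < 0.01
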