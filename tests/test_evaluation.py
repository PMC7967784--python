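"""Tests for fold assignment, CV metrics and the NB/KNN reference baselines."""

import math

import pytest

from conftest import make_record
from sinkcod.evaluation import (
    EvaluationReport,
    cross_validate,
    f1_distribution,
    kfold_split,
    knn_baseline,
    naive_bayes_baseline,
    score_predictions,
)
from sinkcod.records import Gender


class TestKFoldSplit:
    def test_k_records_k_folds_is_a_perfect_matching(self):
        records = [make_record(f"r{i}", chain=("I10",)) for i in range(17)]
        folds = kfold_split(records, k=17, seed=0)
        assert sorted(folds.fold_sizes()) == [1] * 17

    def test_partition_is_disjoint_and_exhaustive(self, small_cohort):
        folds = kfold_split(small_cohort, k=17, seed=3)
        assert set(folds.assignment) == {r.record_id for r in small_cohort}
        sizes = folds.fold_sizes()
        assert sum(sizes) == len(small_cohort)
        assert max(sizes) - min(sizes) <= 1

    def test_seed_controls_the_assignment(self, small_cohort):
        a = kfold_split(small_cohort, k=17, seed=1).assignment
        b = kfold_split(small_cohort, k=17, seed=1).assignment
        c = kfold_split(small_cohort, k=17, seed=2).assignment
        assert a == b
        assert a != c

    def test_stratified_split_spreads_labels_and_stays_balanced(self, small_cohort):
        folds = kfold_split(small_cohort, k=10, seed=4, stratify=True)
        sizes = folds.fold_sizes()
        assert max(sizes) - min(sizes) <= 1
        by_label = {}
        for r in small_cohort:
            by_label.setdefault(r.underlying.code, []).append(
                folds.fold_of(r.record_id)
            )
        for label, assigned in by_label.items():
            counts = [assigned.count(f) for f in range(10)]
            assert max(counts) - min(counts) <= 1, label

    def test_k_larger_than_cohort_rejected(self):
        records = [make_record(f"r{i}", chain=("I10",)) for i in range(5)]
        with pytest.raises(ValueError):
            kfold_split(records, k=6, seed=0)


class TestScorePredictions:
    def test_perfect_predictions_score_one_everywhere(self):
        y = ["I10", "J60", "I10", "C34.9"]
        report = score_predictions(y, list(y))
        assert report.macro_f1 == 1.0 and report.micro_f1 == 1.0
        assert all(f == 1.0 for (_, _, f, s) in report.per_cause.values())

    def test_hand_computed_confusion(self):
        # cause X: tp=2, fp=1, fn=0 -> precision 2/3, recall 1, F1 0.8
        y_true = ["X00", "X00", "Y10", "Y10", "Y10", "Y10"]
        y_pred = ["X00", "X00", "X00", "Y10", "Y10", "Y10"]
        report = score_predictions(y_true, y_pred)
        p, r, f, s = report.per_cause["X00"]
        assert (p, r, s) == pytest.approx((2 / 3, 1.0, 2))
        assert f == pytest.approx(0.8)

    def test_micro_precision_recall_f1_coincide(self, small_cohort):
        y_true = [r.underlying.code for r in small_cohort]
        y_pred = [r.chain[0].code for r in small_cohort]
        report = score_predictions(y_true, y_pred)
        assert report.micro_precision == report.micro_recall == report.micro_f1


class TestF1Distribution:
    def make_report(self, f1s):
        return EvaluationReport(
            per_cause={f"C{i:02d}": (1.0, 1.0, f, 1) for i, f in enumerate(f1s)},
            macro_precision=1.0, macro_recall=1.0, macro_f1=1.0,
            micro_precision=1.0, micro_recall=1.0, micro_f1=1.0,
        )

    def test_all_perfect(self):
        assert f1_distribution(self.make_report([1.0] * 4), [0.95]) == {0.95: 1.0}

    def test_direct_count(self):
        dist = f1_distribution(self.make_report([1.0, 0.9, 0.5, 0.2]), [0.7])
        assert dist == {0.7: 0.5}

    def test_non_increasing_in_threshold(self):
        dist = f1_distribution(self.make_report([1.0, 0.9, 0.5, 0.2]), [0.7, 0.95])
        assert dist[0.95] <= dist[0.7]

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            f1_distribution(self.make_report([]))


class TestCrossValidate:
    def test_report_is_reproducible_and_bounded(self, small_cohort):
        a = cross_validate(small_cohort, k=5, seed=9)
        b = cross_validate(small_cohort, k=5, seed=9)
        assert a.to_dict() == b.to_dict()
        assert 0.0 <= a.macro_f1 <= 1.0
        assert a.n_records == len(small_cohort)

    def test_per_fold_macro_f1_has_one_entry_per_fold(self, small_cohort):
        report = cross_validate(small_cohort, k=5, seed=9, per_fold=True)
        assert len(report.per_fold_macro_f1) == 5
        assert all(0.0 <= f <= 1.0 for f in report.per_fold_macro_f1)


def nb_fixture():
    """Seven labeled records, two classes, posteriors computable by hand."""
    train = [
        make_record("t1", age=70, chain=("I10", "J60"), underlying="J60"),
        make_record("t2", age=72, chain=("I10", "J60"), underlying="J60"),
        make_record("t3", age=75, chain=("J60",), underlying="J60"),
        make_record("t4", age=71, chain=("I10",), underlying="I10"),
        make_record("t5", age=74, chain=("I10", "C34.9"), underlying="I10"),
        make_record("t6", age=73, chain=("I10",), underlying="I10"),
        make_record("t7", age=77, chain=("J60",), underlying="J60"),
    ]
    test = make_record("q1", age=76, chain=("I10", "J60"))
    return train, test


class TestNaiveBayes:
    def test_degenerate_posterior_predicts_the_always_underlying_cause(self):
        train = [
            make_record(f"a{i}", chain=("C34.9", "I10"), underlying="C34.9")
            for i in range(10)
        ]
        (result,) = naive_bayes_baseline(train, [make_record("q", chain=("C34.9", "I10"))])
        assert result.predicted.code == "C34.9"

    def test_manual_posterior_oracle_on_six_record_fixture(self):
        train, test = nb_fixture()
        (result,) = naive_bayes_baseline(train, [test], smoothing_alpha=1.0)
        # Hand computation, alpha=1. Class counts: J60:4, I10:3, n=7; all
        # records are old males, so those factors still differ only via
        # the class-count denominators.
        cause_counts = {
            ("J60", "I10"): 2, ("J60", "J60"): 4,
            ("I10", "I10"): 3, ("I10", "J60"): 2,
        }
        class_counts = {"J60": 4, "I10": 3}

        def manual(u, present):
            nc = class_counts[u]
            lp = math.log((nc + 1) / (7 + 2))
            for code in present:
                lp += math.log((cause_counts.get((u, code), 0) + 1) / (nc + 2))
            lp += math.log((nc + 1) / (nc + 3))  # age group old
            lp += math.log((nc + 1) / (nc + 2))  # gender male
            return lp

        expected = {u: manual(u, ["I10", "J60"]) for u in ("I10", "J60")}
        assert expected["J60"] > expected["I10"]  # genuinely decided, not a tie
        assert result.predicted.code == "J60"
        assert result.score == pytest.approx(expected["J60"])

    def test_restriction_to_candidate_set(self):
        train = [
            make_record("t1", chain=("I10",), underlying="I10"),
            make_record("t2", chain=("J60",), underlying="J60"),
            make_record("t3", chain=("J60",), underlying="J60"),
        ]
        # candidate set of the test record excludes the globally likelier J60
        (result,) = naive_bayes_baseline(train, [make_record("q", chain=("I10",))])
        assert result.predicted.code == "I10"

    def test_deterministic_across_repeat_runs(self, small_cohort):
        train, test = small_cohort[:1500], small_cohort[1500:1600]
        a = naive_bayes_baseline(train, test)
        b = naive_bayes_baseline(train, test)
        assert a == b

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            naive_bayes_baseline([], [make_record("q", chain=("I10",))])


class TestKNN:
    def test_exact_match_with_k1_returns_its_label(self):
        train = [
            make_record("t1", age=70, chain=("I10", "J60"), underlying="J60"),
            make_record("t2", age=30, chain=("C34.9",), underlying="C34.9"),
        ]
        test = make_record("q", age=70, chain=("I10", "J60"))
        (result,) = knn_baseline(train, [test], k_neighbors=1)
        assert result.predicted.code == "J60"

    def test_majority_vote_on_hand_countable_fixture(self):
        # distances to q (chain {I10,J60}, old male):
        #  t1 {I10,J60} old male  -> 0 (label J60)
        #  t2 {I10}     old male  -> 1 (label I10)
        #  t3 {I10,J60} old female-> 1 (label J60)
        #  t4 {C34.9}   young male-> 4 (label C34.9)
        #  t5 {A41.9}   old male  -> 3 (label A41.9)
        train = [
            make_record("t1", age=70, chain=("I10", "J60"), underlying="J60"),
            make_record("t2", age=70, chain=("I10",), underlying="I10"),
            make_record("t3", age=70, gender=Gender.FEMALE, chain=("I10", "J60"),
                        underlying="J60"),
            make_record("t4", age=10, chain=("C34.9",), underlying="C34.9"),
            make_record("t5", age=70, chain=("A41.9",), underlying="A41.9"),
        ]
        test = make_record("q", age=70, chain=("I10", "J60"))
        (result,) = knn_baseline(train, [test], k_neighbors=3)
        assert result.predicted.code == "J60"
        assert result.score == pytest.approx(2 / 3)

    def test_training_order_invariance(self, small_cohort):
        train, test = small_cohort[:400], small_cohort[400:450]
        a = knn_baseline(train, test, k_neighbors=5)
        b = knn_baseline(list(reversed(train)), test, k_neighbors=5)
        assert a == b

    def test_k_exceeding_training_size_rejected(self):
        train = [make_record("t1", chain=("I10",), underlying="I10")]
        with pytest.raises(ValueError):
            knn_baseline(train, [make_record("q", chain=("I10",))], k_neighbors=2)
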