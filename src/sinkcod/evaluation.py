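"""Cross-validated evaluation of underlying-cause inference.

The protocol: split the labeled cohort into *k* folds (default 17),
train the count/CDCP tables on k−1 folds, infer the held-out fold, pool
all held-out predictions and score them per cause with one-vs-rest
precision, recall and F1, plus macro/micro aggregates and the fraction
of causes whose F1 exceeds given thresholds.

Two reference baselines cast the task as ordinary classification:

* **Naive Bayes** — features are the presence of each cause on the
  record plus age group and gender, assumed independent given the
  underlying-cause class; additive smoothing; argmax posterior,
  restricted to the record's candidate set by default.
* **KNN** — Hamming distance on (multi-hot cause vector, age group,
  gender); majority label among the k nearest training records.

Both baselines are deterministic given their tie rules (smallest
distance sum, then lexicographic label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .estimation import accumulate_counts, compute_cdcp
from .inference import InferenceOptions, InferenceResult, sink_infer_batch
from .records import AgeGroup, CauseCode, DeathRecord, require_labeled

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "EstimatorConfig",
    "kfold_split",
    "score_predictions",
    "cross_validate",
    "f1_distribution",
    "naive_bayes_baseline",
    "knn_baseline",
]

DEFAULT_THRESHOLDS = (0.5, 0.7, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of record_ids into k folds of near-equal size."""

    k: int
    seed: int
    assignment: Dict[str, int]

    def fold_of(self, record_id: str) -> int:
        return self.assignment[record_id]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes


@dataclass(frozen=True)
class EstimatorConfig:
    """How the CDCP table is fitted inside each CV turn."""

    transform: str = "raw"
    smoothing_alpha: float = 0.0
    include_history: bool = True


@dataclass
class EvaluationReport:
    """Per-cause and aggregate metrics from pooled held-out predictions."""

    per_cause: Dict[str, Tuple[float, float, float, int]]  # precision, recall, f1, support
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    f1_fraction_above: Dict[float, float] = field(default_factory=dict)
    n_records: int = 0
    per_fold_macro_f1: Optional[list[float]] = None

    def to_dict(self) -> dict:
        return {
            "per_cause": {
                c: {"precision": p, "recall": r, "f1": f, "support": s}
                for c, (p, r, f, s) in sorted(self.per_cause.items())
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "f1_fraction_above": {str(t): v for t, v in self.f1_fraction_above.items()},
            "n_records": self.n_records,
            "per_fold_macro_f1": self.per_fold_macro_f1,
        }


def kfold_split(
    records: Sequence[DeathRecord], k: int = 17, seed: int = 0, stratify: bool = False
) -> FoldAssignment:
    """Assign records to k folds: seeded shuffle then round-robin.

    With ``stratify`` the round-robin runs within each underlying-cause
    label group (in shuffled order), spreading rare causes across folds
    while keeping overall fold sizes within one of each other.
    """
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of records ({len(records)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    if stratify:
        require_labeled(records)
        # stable sort by label over the shuffled order keeps the shuffle
        # within each label group, then one global round-robin counter
        # keeps fold sizes balanced overall.
        labels = [records[i].underlying.code for i in perm]
        order = perm[np.argsort(labels, kind="stable")]
    else:
        order = perm
    assignment = {records[i].record_id: pos % k for pos, i in enumerate(order)}
    if len(assignment) != len(records):
        raise ValueError("record_ids must be unique for fold assignment")
    return FoldAssignment(k=k, seed=seed, assignment=assignment)


def score_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> EvaluationReport:
    """One-vs-rest per-cause metrics plus macro/micro aggregates.

    Macro averages run over causes actually present in the labels
    (support ≥ 1); per-cause entries additionally cover causes that were
    only ever predicted (support 0, precision meaningful).  In this
    single-label setting micro precision = recall = F1 = accuracy.
    """
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    all_labels = sorted(set(y_true) | set(y_pred))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=all_labels, zero_division=0
    )
    per_cause = {
        lab: (float(p), float(r), float(f), int(s))
        for lab, p, r, f, s in zip(all_labels, prec, rec, f1, supp)
    }
    present = [lab for lab in all_labels if per_cause[lab][3] > 0]
    macro_p = float(np.mean([per_cause[lab][0] for lab in present]))
    macro_r = float(np.mean([per_cause[lab][1] for lab in present]))
    macro_f = float(np.mean([per_cause[lab][2] for lab in present]))
    accuracy = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    report = EvaluationReport(
        per_cause=per_cause,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        micro_precision=accuracy,
        micro_recall=accuracy,
        micro_f1=accuracy,
        n_records=len(y_true),
    )
    report.f1_fraction_above = f1_distribution(report, thresholds)
    return report


def f1_distribution(
    report: EvaluationReport, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> Dict[float, float]:
    """Fraction of causes (support ≥ 1) whose F1 exceeds each threshold."""
    f1s = [f for (_, _, f, s) in report.per_cause.values() if s >= 1]
    if not f1s:
        raise ValueError("report has no causes with support ≥ 1")
    return {float(t): sum(f > t for f in f1s) / len(f1s) for t in thresholds}


def cross_validate(
    records: Sequence[DeathRecord],
    k: int = 17,
    seed: int = 0,
    estimator_config: EstimatorConfig = EstimatorConfig(),
    inference_options: InferenceOptions = InferenceOptions(),
    stratify: bool = False,
    per_fold: bool = False,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> EvaluationReport:
    """k-fold cross-validation of the sink algorithm.

    Each fold is held out exactly once; the count and CDCP tables are
    fitted strictly on the other k−1 folds (no leakage).  Held-out
    predictions are pooled before scoring, which keeps metrics defined
    for rare causes; ``per_fold`` additionally reports per-fold macro F1.
    """
    require_labeled(records)
    folds = kfold_split(records, k=k, seed=seed, stratify=stratify)
    y_true: list[str] = []
    y_pred: list[str] = []
    fold_macro: list[float] = []
    for fold in range(k):
        train = [r for r in records if folds.fold_of(r.record_id) != fold]
        test = [r for r in records if folds.fold_of(r.record_id) == fold]
        counts = accumulate_counts(train, include_history=estimator_config.include_history)
        cdcp = compute_cdcp(
            counts,
            transform=estimator_config.transform,
            smoothing_alpha=estimator_config.smoothing_alpha,
        )
        results = sink_infer_batch(test, cdcp, inference_options)
        fold_true = [r.underlying.code for r in test]
        fold_pred = [res.predicted.code for res in results]
        y_true.extend(fold_true)
        y_pred.extend(fold_pred)
        if per_fold:
            fold_macro.append(score_predictions(fold_true, fold_pred, thresholds).macro_f1)
    report = score_predictions(y_true, y_pred, thresholds)
    if per_fold:
        report.per_fold_macro_f1 = fold_macro
    return report


# ---------------------------------------------------------------------------
# Reference baselines


def _feature_space(records: Sequence[DeathRecord]) -> list[str]:
    vocab = set()
    for r in records:
        vocab.update(c.code for c in r.chain)
        vocab.update(c.code for c in r.history)
    return sorted(vocab)


def _record_codes(r: DeathRecord) -> frozenset:
    return frozenset(c.code for c in r.chain) | frozenset(c.code for c in r.history)


def naive_bayes_baseline(
    train_records: Sequence[DeathRecord],
    test_records: Sequence[DeathRecord],
    smoothing_alpha: float = 1.0,
    restrict_to_candidates: bool = True,
) -> list[InferenceResult]:
    """Naive Bayes over cause-presence, age-group and gender features.

    All causes on the record are treated as independent given the
    underlying-cause class: the class score is the prior times the
    per-class conditional of each present cause, of the age group and
    of the gender, each with additive smoothing.  Prediction is the
    argmax over the record's candidate set (or over all classes when
    ``restrict_to_candidates`` is off); ties break lexicographically.
    """
    if not train_records:
        raise ValueError("empty training set")
    require_labeled(train_records)
    class_count: Dict[str, int] = {}
    cause_given_class: Dict[Tuple[str, str], int] = {}
    ag_given_class: Dict[Tuple[str, AgeGroup], int] = {}
    g_given_class: Dict[Tuple[str, str], int] = {}
    for r in train_records:
        u = r.underlying.code
        class_count[u] = class_count.get(u, 0) + 1
        for code in _record_codes(r):
            cause_given_class[(u, code)] = cause_given_class.get((u, code), 0) + 1
        ag_given_class[(u, r.age_group)] = ag_given_class.get((u, r.age_group), 0) + 1
        g_given_class[(u, r.gender.value)] = g_given_class.get((u, r.gender.value), 0) + 1
    n_train = len(train_records)
    classes = sorted(class_count)
    a = smoothing_alpha

    def log_posterior(r: DeathRecord, u: str) -> float:
        nc = class_count.get(u, 0)
        lp = math.log((nc + a) / (n_train + a * len(classes)))
        for code in _record_codes(r):
            lp += math.log((cause_given_class.get((u, code), 0) + a) / (nc + 2 * a))
        lp += math.log((ag_given_class.get((u, r.age_group), 0) + a) / (nc + 3 * a))
        lp += math.log((g_given_class.get((u, r.gender.value), 0) + a) / (nc + 2 * a))
        return lp

    results = []
    for r in test_records:
        if restrict_to_candidates:
            pool = [c.code for c in r.candidates(include_history=True)]
            pool = [c for c in pool if c in class_count] or [c.code for c in r.candidates()]
        else:
            pool = classes
        scores = {u: log_posterior(r, u) for u in set(pool)}
        best_score = max(scores.values())
        tied = sorted(u for u, s in scores.items() if s == best_score)
        best = tied[0]
        pred = _resolve_code(r, best)
        results.append(
            InferenceResult(
                record_id=r.record_id,
                predicted=pred,
                score=best_score,
                source="chain",
                tie_broken=len(tied) > 1,
            )
        )
    return results


def _resolve_code(r: DeathRecord, code: str) -> CauseCode:
    for c in r.candidates(include_history=True):
        if c.code == code:
            return c
    return CauseCode(code)


def knn_baseline(
    train_records: Sequence[DeathRecord],
    test_records: Sequence[DeathRecord],
    k_neighbors: int = 5,
) -> list[InferenceResult]:
    """K-nearest-neighbour baseline on Hamming distance.

    Distance between two records = size of the symmetric difference of
    their cause-code sets, plus 1 if the age groups differ, plus 1 if
    the genders differ.  The majority underlying label among the k
    nearest training records wins; label ties go to the smallest
    summed distance, then lexicographic order.  Neighbour selection at
    equal distance is by training record_id, making the result
    invariant to training-set order.
    """
    if not train_records:
        raise ValueError("empty training set")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be ≥ 1")
    if k_neighbors > len(train_records):
        raise ValueError("k_neighbors exceeds the training-set size")
    require_labeled(train_records)
    vocab = {c: i for i, c in enumerate(_feature_space(list(train_records) + list(test_records)))}
    ags = {AgeGroup.YOUNG: 0, AgeGroup.MIDDLE: 1, AgeGroup.OLD: 2}

    def encode(recs: Sequence[DeathRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = np.zeros((len(recs), len(vocab)), dtype=np.int8)
        ag = np.empty(len(recs), dtype=np.int64)
        g = np.empty(len(recs), dtype=np.int64)
        for i, r in enumerate(recs):
            for code in _record_codes(r):
                X[i, vocab[code]] = 1
            ag[i] = ags[r.age_group]
            g[i] = 0 if r.gender.value == "male" else 1
        return X, ag, g

    Xtr, ag_tr, g_tr = encode(train_records)
    Xte, ag_te, g_te = encode(test_records)
    labels = np.array([r.underlying.code for r in train_records])
    # deterministic secondary order: training record_id
    id_rank = np.argsort(np.argsort([r.record_id for r in train_records], kind="stable"))
    sizes_tr = Xtr.sum(axis=1).astype(np.int64)

    results = []
    chunk = max(1, 2_000_000 // max(1, len(train_records)))
    for start in range(0, len(test_records), chunk):
        sl = slice(start, min(start + chunk, len(test_records)))
        inter = Xte[sl].astype(np.int64) @ Xtr.T.astype(np.int64)
        ham = (
            sizes_tr[None, :]
            + Xte[sl].sum(axis=1, dtype=np.int64)[:, None]
            - 2 * inter
            + (ag_tr[None, :] != ag_te[sl, None]).astype(np.int64)
            + (g_tr[None, :] != g_te[sl, None]).astype(np.int64)
        )
        for row, r in zip(ham, test_records[sl.start : sl.stop]):
            order = np.lexsort((id_rank, row))[:k_neighbors]
            votes: Dict[str, list] = {}
            for j in order:
                v = votes.setdefault(labels[j], [0, 0])
                v[0] += 1
                v[1] += int(row[j])
            best = min(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
            tied = sum(
                1
                for kv in votes.items()
                if (-kv[1][0], kv[1][1]) == (-best[1][0], best[1][1])
            )
            results.append(
                InferenceResult(
                    record_id=r.record_id,
                    predicted=_resolve_code(r, best[0]),
                    score=float(best[1][0]) / k_neighbors,
                    source="chain",
                    tie_broken=tied > 1,
                )
            )
    return results
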