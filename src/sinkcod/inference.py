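"""The sink algorithm: pick the candidate cause with maximal CDCP.

A decedent is modeled as a boat and the causes on the certificate as
stones loaded into it; the underlying cause-of-death is the heaviest
stone — the candidate with the largest conditional death cause
proportion (CDCP) in the decedent's age/gender stratum.

Two special rules sit around the argmax:

* **External-cause short-circuit** (on by default): when the direct
  cause (chain position A) is an ICD-10 Chapter XX external cause, it
  is the underlying cause by definition and no lookup happens.
* **Fallback**: candidates whose CDCP is absent even after the lookup
  fallback chain are excluded; if every candidate is absent the direct
  cause is predicted with ``source="fallback"``.

Ties on the score are broken deterministically: the candidate latest in
the chain wins (the chain runs from the direct cause backwards toward
the originating condition), chain candidates beat history candidates,
and remaining ties fall to lexicographic code order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .estimation import CDCPTable, lookup_cdcp
from .records import CauseCode, DeathRecord, RecordValidationError

__all__ = ["InferenceOptions", "InferenceResult", "sink_infer", "sink_infer_batch"]


@dataclass(frozen=True)
class InferenceOptions:
    """Knobs for :func:`sink_infer`.

    ``external_rule`` enables the direct-cause short-circuit for
    external causes; ``include_history`` admits past-medical-history
    codes into the candidate set; ``fallback_policy`` is passed through
    to :func:`~sinkcod.estimation.lookup_cdcp`.
    """

    external_rule: bool = True
    include_history: bool = True
    fallback_policy: str = "pooled"


@dataclass(frozen=True)
class InferenceResult:
    record_id: str
    predicted: CauseCode
    score: Optional[float]
    source: str  # chain | history | external_rule | fallback
    tie_broken: bool = False


def _tie_rank(record: DeathRecord, cause: CauseCode) -> tuple:
    """Sort key among equal-score candidates; the minimum wins.

    Chain candidates come first, later chain positions preferred;
    history candidates follow in lexicographic code order.
    """
    for pos, c in enumerate(record.chain):
        if c.code == cause.code:
            return (0, -pos, c.code)
    return (1, 0, cause.code)


def sink_infer(
    record: DeathRecord,
    cdcp: CDCPTable,
    options: InferenceOptions = InferenceOptions(),
) -> InferenceResult:
    """Infer the underlying cause-of-death for one record.

    Scores every candidate (chain, plus history when enabled) with a
    stratum-specific CDCP lookup and predicts the maximum; see the
    module docstring for the external rule, fallback and tie handling.
    """
    if len(record.chain) == 0:
        raise RecordValidationError(f"record {record.record_id}: empty chain")
    direct = record.direct_cause
    if options.external_rule and direct.is_external:
        return InferenceResult(
            record_id=record.record_id,
            predicted=direct,
            score=None,
            source="external_rule",
        )
    scored: list[tuple[CauseCode, float]] = []
    for cause in record.candidates(include_history=options.include_history):
        value = lookup_cdcp(
            cdcp, cause, record.age_group, record.gender, options.fallback_policy
        )
        if value is not None:
            scored.append((cause, value))
    if not scored:
        return InferenceResult(
            record_id=record.record_id,
            predicted=direct,
            score=None,
            source="fallback",
        )
    best_score = max(s for _, s in scored)
    tied = [c for c, s in scored if s == best_score]
    winner = min(tied, key=lambda c: _tie_rank(record, c))
    in_chain = any(c.code == winner.code for c in record.chain)
    return InferenceResult(
        record_id=record.record_id,
        predicted=winner,
        score=best_score,
        source="chain" if in_chain else "history",
        tie_broken=len(tied) > 1,
    )


def sink_infer_batch(
    records: Sequence[DeathRecord],
    cdcp: CDCPTable,
    options: InferenceOptions = InferenceOptions(),
) -> list[InferenceResult]:
    """Element-wise :func:`sink_infer`; order preserved, records independent."""
    results = []
    errors = []
    for record in records:
        try:
            results.append(sink_infer(record, cdcp, options))
        except RecordValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise RecordValidationError(
            f"{len(errors)} records failed inference: " + "; ".join(errors[:5])
        )
    return results
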