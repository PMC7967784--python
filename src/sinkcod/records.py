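"""Domain types for death records and ICD-10 cause codes, plus CSV I/O.

A death record describes one decedent: demographic stratifiers (age,
gender, region), the ordered cause-of-death chain from the death
certificate (direct cause first, up to four entries), any past-medical-
history codes, and — for labeled data — the underlying cause-of-death.

Codes follow WHO's ICD-10 syntax: one letter, two digits, and an
optional sub-code after a dot (``I25.1``, ``J60``). Chapter XX codes
(leading letter V, W, X or Y) denote external causes of death (injury
mechanisms); everything else is an internal cause.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CauseCode",
    "Gender",
    "AgeGroup",
    "DeathRecord",
    "RecordValidationError",
    "SchemaError",
    "parse_icd10",
    "read_records",
    "write_records",
    "RECORD_COLUMNS",
]

#: ICD-10 code syntax: letter, two digits, optional dot plus 1-2 alphanumerics.
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[A-Z0-9]{1,2})?$")

#: Leading letters of ICD-10 Chapter XX (external causes, V01-Y98).
EXTERNAL_CHAPTER_LETTERS = frozenset("VWXY")

RECORD_COLUMNS = [
    "record_id",
    "age",
    "sex",
    "region",
    "cause_a",
    "cause_b",
    "cause_c",
    "cause_d",
    "history",
    "underlying",
]

_REQUIRED_COLUMNS = ["record_id", "age", "sex", "region", "cause_a"]


class RecordValidationError(ValueError):
    """A record (or a raw code string) violates a domain invariant."""


class SchemaError(ValueError):
    """An input file is missing required columns or metadata."""


@dataclass(frozen=True, order=True)
class CauseCode:
    """A normalized ICD-10 cause-of-death code.

    ``is_external`` is derived from the leading letter: V/W/X/Y codes
    are external causes (Chapter XX), everything else internal.
    """

    code: str
    is_external: bool = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if not ICD10_PATTERN.match(self.code):
            raise RecordValidationError(
                f"not a syntactically valid ICD-10 code: {self.code!r}"
            )
        object.__setattr__(self, "is_external", self.code[0] in EXTERNAL_CHAPTER_LETTERS)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def parse_icd10(raw: str) -> CauseCode:
    """Parse and normalize a raw ICD-10 string into a :class:`CauseCode`.

    Normalization uppercases and strips whitespace; the dot in 4+
    character codes is preserved. Raises :class:`RecordValidationError`
    for anything that does not match the ICD-10 syntax.
    """
    if raw is None:
        raise RecordValidationError("ICD-10 code is missing")
    cleaned = str(raw).strip().upper()
    if not cleaned:
        raise RecordValidationError("ICD-10 code is empty")
    return CauseCode(cleaned)


class Gender(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, raw: str) -> "Gender":
        v = str(raw).strip().lower()
        aliases = {"m": "male", "f": "female", "male": "male", "female": "female"}
        if v not in aliases:
            raise RecordValidationError(f"unknown gender value: {raw!r}")
        return cls(aliases[v])


class AgeGroup(enum.Enum):
    """Three-level age stratification: young (≤18), middle (18–55 exclusive), old (≥55)."""

    YOUNG = "young"
    MIDDLE = "middle"
    OLD = "old"

    @classmethod
    def from_age(cls, age: int) -> "AgeGroup":
        if age < 0:
            raise RecordValidationError(f"age must be non-negative, got {age}")
        if age <= 18:
            return cls.YOUNG
        if age < 55:
            return cls.MIDDLE
        return cls.OLD


@dataclass(frozen=True)
class DeathRecord:
    """One decedent's certificate data.

    ``chain`` is the ordered cause-of-death chain with the direct cause
    at position 0 and at most four entries; entries are pairwise
    distinct because chain positions carry causal order. ``history``
    holds past-medical-history codes that may still be the underlying
    cause. ``underlying``, when present, must come from chain∪history.
    """

    record_id: str
    age: int
    gender: Gender
    region: str
    chain: tuple[CauseCode, ...]
    history: tuple[CauseCode, ...] = ()
    underlying: Optional[CauseCode] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chain", tuple(self.chain))
        object.__setattr__(self, "history", tuple(self.history))
        if not isinstance(self.age, int) or isinstance(self.age, bool):
            raise RecordValidationError(
                f"record {self.record_id}: age must be an integer, got {self.age!r}"
            )
        if self.age < 0:
            raise RecordValidationError(
                f"record {self.record_id}: age must be ≥ 0, got {self.age}"
            )
        if not 1 <= len(self.chain) <= 4:
            raise RecordValidationError(
                f"record {self.record_id}: chain must have 1-4 causes, "
                f"got {len(self.chain)}"
            )
        if len({c.code for c in self.chain}) != len(self.chain):
            raise RecordValidationError(
                f"record {self.record_id}: duplicate codes in chain"
            )
        if self.underlying is not None:
            members = {c.code for c in self.chain} | {c.code for c in self.history}
            if self.underlying.code not in members:
                raise RecordValidationError(
                    f"record {self.record_id}: underlying cause "
                    f"{self.underlying.code} not in chain or history"
                )

    @property
    def age_group(self) -> AgeGroup:
        return AgeGroup.from_age(self.age)

    @property
    def direct_cause(self) -> CauseCode:
        return self.chain[0]

    def candidates(self, include_history: bool = True) -> tuple[CauseCode, ...]:
        """Distinct candidate underlying causes, chain first in chain order."""
        seen = {c.code for c in self.chain}
        cands = list(self.chain)
        if include_history:
            for c in self.history:
                if c.code not in seen:
                    seen.add(c.code)
                    cands.append(c)
        return tuple(cands)


def _row_to_record(row: pd.Series) -> DeathRecord:
    chain = []
    for col in ("cause_a", "cause_b", "cause_c", "cause_d"):
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
            continue
        chain.append(parse_icd10(raw))
    history_raw = row.get("history")
    history = []
    if history_raw is not None and not (isinstance(history_raw, float) and pd.isna(history_raw)):
        for part in str(history_raw).split(";"):
            if part.strip():
                history.append(parse_icd10(part))
    underlying_raw = row.get("underlying")
    underlying = None
    if underlying_raw is not None and not (
        isinstance(underlying_raw, float) and pd.isna(underlying_raw)
    ):
        if str(underlying_raw).strip():
            underlying = parse_icd10(underlying_raw)
    try:
        age = int(str(row["age"]).strip())
    except (TypeError, ValueError) as exc:
        raise RecordValidationError(
            f"record {row['record_id']}: age {row['age']!r} is not an integer"
        ) from exc
    return DeathRecord(
        record_id=str(row["record_id"]),
        age=age,
        gender=Gender.parse(row["sex"]),
        region=str(row["region"]).strip(),
        chain=tuple(chain),
        history=tuple(history),
        underlying=underlying,
    )


def read_records(path: Union[str, Path], strict: bool = True) -> list[DeathRecord]:
    """Read death records from a comma-delimited file with a header row.

    Required columns: ``record_id, age, sex, region, cause_a``; optional
    ``cause_b..d``, ``history`` (semicolon-separated) and ``underlying``.
    In strict mode (default) a row violating an invariant aborts the
    read; in lenient mode offending rows are skipped and the skip count
    is logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    records: list[DeathRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except RecordValidationError as exc:
            if strict:
                raise
            skipped += 1
            logger.warning("skipping invalid row: %s", exc)
    if skipped:
        logger.info("read_records: skipped %d invalid rows", skipped)
    return records


def write_records(records: Iterable[DeathRecord], path: Union[str, Path]) -> None:
    """Write records to the canonical CSV dialect (round-trip stable)."""
    rows = []
    for r in records:
        chain = list(r.chain) + [None] * (4 - len(r.chain))
        rows.append(
            {
                "record_id": r.record_id,
                "age": r.age,
                "sex": r.gender.value,
                "region": r.region,
                "cause_a": chain[0].code if chain[0] else "",
                "cause_b": chain[1].code if chain[1] else "",
                "cause_c": chain[2].code if chain[2] else "",
                "cause_d": chain[3].code if chain[3] else "",
                "history": ";".join(c.code for c in r.history),
                "underlying": r.underlying.code if r.underlying else "",
            }
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False)


def require_labeled(records: Sequence[DeathRecord]) -> None:
    """Raise if any record lacks an underlying-cause label."""
    for r in records:
        if r.underlying is None:
            raise RecordValidationError(
                f"record {r.record_id} has no underlying-cause label"
            )
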