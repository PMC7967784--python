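"""Worked-example CDCP lookup for four ICD-10 causes.

A published stratified CDCP table for pneumonia (J18.9), intracerebral
haemorrhage (I61.9), other respiratory disorders (J98.4) and sepsis
(A41.9) serves as a fixed, desk-scale fixture: loading one stratum
column as a raw CDCP table and running the sink rule on a decedent
carrying all four causes demonstrates the algorithm on real-world
numbers without any registry extract.  In every adult stratum the
haemorrhage dominates; in the youngest group pneumonia does — the kind
of age reversal the stratified estimator exists to capture.
"""

from __future__ import annotations

from .estimation import CDCPTable
from .records import AgeGroup, CauseCode, DeathRecord, Gender

__all__ = ["WORKED_EXAMPLE_CDCP", "worked_example_table", "worked_example_record"]

#: Published raw CDCP values per stratum column.  "overall" is the
#: unstratified value; the remaining keys are single-stratifier columns.
WORKED_EXAMPLE_CDCP: dict[str, dict[str, float]] = {
    "J18.9": {
        "overall": 0.28514949,
        "male": 0.2663358,
        "female": 0.31307550,
        "young": 0.303030,
        "middle": 0.2550335,
        "old": 0.2861578,
    },
    "I61.9": {
        "overall": 0.8600605,
        "male": 0.8740831,
        "female": 0.83730158,
        "young": 0.285714,
        "middle": 0.88851351,
        "old": 0.85574092,
    },
    "J98.4": {
        "overall": 0.14804722,
        "male": 0.1426710,
        "female": 0.1548254,
        "young": 0.1176470,
        "middle": 0.122362,
        "old": 0.14930489,
    },
    "A41.9": {
        "overall": 0.01851851,
        "male": 0.016194331,
        "female": 0.02162162,
        "young": 0.1379310,
        "middle": 0.0133333,
        "old": 0.01447368,
    },
}

_GENDER_COLUMNS = {"male": Gender.MALE, "female": Gender.FEMALE}
_AGE_COLUMNS = {"young": AgeGroup.YOUNG, "middle": AgeGroup.MIDDLE, "old": AgeGroup.OLD}
#: A representative age inside each age-group column.
_AGE_FOR_COLUMN = {"young": 10, "middle": 40, "old": 77}


def worked_example_table(column: str) -> CDCPTable:
    """Raw CDCP table loaded from one stratum column of the fixture.

    A gender column fills that gender's cells across all age groups; an
    age column fills that age group's cells for both genders; "overall"
    fills every cell.
    """
    table = CDCPTable(transform="raw", smoothing_alpha=0.0)
    for code, columns in WORKED_EXAMPLE_CDCP.items():
        value = columns[column]
        if column in _GENDER_COLUMNS:
            strata = [(ag, _GENDER_COLUMNS[column]) for ag in AgeGroup]
        elif column in _AGE_COLUMNS:
            strata = [(_AGE_COLUMNS[column], g) for g in Gender]
        elif column == "overall":
            strata = [(ag, g) for ag in AgeGroup for g in Gender]
        else:
            raise ValueError(f"unknown worked-example column: {column!r}")
        for ag, g in strata:
            table.cells[(code, ag, g)] = value
    return table


def worked_example_record(column: str) -> DeathRecord:
    """A decedent carrying all four fixture causes, in the column's stratum."""
    if column in _GENDER_COLUMNS:
        gender, age = _GENDER_COLUMNS[column], 77
    elif column in _AGE_COLUMNS:
        gender, age = Gender.MALE, _AGE_FOR_COLUMN[column]
    elif column == "overall":
        gender, age = Gender.MALE, 77
    else:
        raise ValueError(f"unknown worked-example column: {column!r}")
    return DeathRecord(
        record_id=f"example-{column}",
        age=age,
        gender=gender,
        region="example",
        chain=tuple(CauseCode(c) for c in WORKED_EXAMPLE_CDCP),
    )
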