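"""Stratified conditional-probability estimators fitted from labeled records.

Two quantities drive the sink algorithm:

* **CDCP** (conditional death cause proportion): the probability that a
  cause is the underlying cause-of-death given that it appears on a
  decedent's certificate, stratified by age group and gender.  The raw
  estimator for a cell is ``death_count / occur_count`` with optional
  additive smoothing ``(d + α) / (o + 2α)``; the log variant transforms
  the raw ratio as ``log2(raw × 10)``.  The transform is strictly
  increasing, so both variants rank causes identically within a stratum.
* **RDCP** (regional death cause proportion): the fraction of deaths in
  a region attributed to each cause as underlying; values sum to one
  within each region.

Counts come from :func:`accumulate_counts`: for each labeled record a
cause's occurrence cell is incremented at most once (a record is one
decedent), and the death cell of the labeled underlying cause is
incremented once.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

from .records import (
    AgeGroup,
    CauseCode,
    DeathRecord,
    Gender,
    RecordValidationError,
    require_labeled,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "CDCPTable",
    "RDCPTable",
    "accumulate_counts",
    "compute_cdcp",
    "compute_rdcp",
    "lookup_cdcp",
    "serialize_table",
    "deserialize_table",
    "FALLBACK_POLICIES",
]

CellKey = Tuple[str, AgeGroup, Gender]

#: How :func:`lookup_cdcp` treats a query whose exact stratum cell is absent.
#: ``pooled`` walks gender-pooled → age-pooled → global cells (each computed
#: from pooled counts); ``stratum`` (alias ``none``) uses the exact cell only.
FALLBACK_POLICIES = ("pooled", "stratum", "none")

_SERIAL_VERSION = 1


def _cell_key_str(code: str, age_group: AgeGroup, gender: Gender) -> str:
    return f"{code}|{age_group.value}|{gender.value}"


def _parse_cell_key(key: str) -> CellKey:
    code, ag, g = key.split("|")
    return code, AgeGroup(ag), Gender(g)


@dataclass
class CountTable:
    """Per (cause, age group, gender) occurrence and underlying-death counts."""

    cells: Dict[CellKey, Tuple[int, int]] = field(default_factory=dict)
    total_records: int = 0
    include_history: bool = True

    def occur(self, code: str, age_group: AgeGroup, gender: Gender) -> int:
        return self.cells.get((code, age_group, gender), (0, 0))[0]

    def deaths(self, code: str, age_group: AgeGroup, gender: Gender) -> int:
        return self.cells.get((code, age_group, gender), (0, 0))[1]

    def validate(self) -> None:
        for key, (occ, dth) in self.cells.items():
            if dth > occ:
                raise ValueError(f"cell {key}: death_count {dth} > occur_count {occ}")
            if occ < 0 or dth < 0:
                raise ValueError(f"cell {key}: negative count")


@dataclass
class CDCPTable:
    """Fitted conditional death cause proportions the sink algorithm looks up.

    ``cells`` maps exact stratum cells to the transformed value.  The
    pooled maps hold fallback values computed from pooled *counts* (not
    averaged proportions): ``gender_pooled`` keys are ``(code, age_group)``,
    ``age_pooled`` keys are ``(code, gender)``, ``global_cells`` keys are
    the bare code.
    """

    transform: str = "raw"
    smoothing_alpha: float = 0.0
    cells: Dict[CellKey, float] = field(default_factory=dict)
    gender_pooled: Dict[Tuple[str, AgeGroup], float] = field(default_factory=dict)
    age_pooled: Dict[Tuple[str, Gender], float] = field(default_factory=dict)
    global_cells: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transform not in ("raw", "log"):
            raise ValueError(f"unknown transform: {self.transform!r}")
        if self.smoothing_alpha < 0:
            raise ValueError("smoothing_alpha must be ≥ 0")


@dataclass
class RDCPTable:
    """Per-region proportion of deaths attributed to each underlying cause."""

    cells: Dict[Tuple[str, str], float] = field(default_factory=dict)  # (region, code)
    region_totals: Dict[str, int] = field(default_factory=dict)

    def rdcp(self, region: str, code: str) -> float:
        return self.cells.get((region, code), 0.0)

    def regions(self) -> list[str]:
        return sorted(self.region_totals)


def accumulate_counts(
    records: Sequence[DeathRecord], include_history: bool = True
) -> CountTable:
    """Accumulate occurrence and underlying-death counts from labeled records.

    Every record must carry an underlying label.  A cause occurring in
    both the chain and the history of one record counts once — the unit
    of counting is the decedent.
    """
    require_labeled(records)
    cells: Dict[CellKey, list] = {}
    for r in records:
        stratum = (r.age_group, r.gender)
        codes = {c.code for c in r.chain}
        if include_history:
            codes |= {c.code for c in r.history}
        for code in codes:
            key = (code, *stratum)
            cell = cells.setdefault(key, [0, 0])
            cell[0] += 1
        ukey = (r.underlying.code, *stratum)
        ucell = cells.setdefault(ukey, [0, 0])
        if r.underlying.code not in codes:
            # underlying sits in history while include_history is off: the
            # decedent still carried the cause, so it occurred once here.
            ucell[0] += 1
        ucell[1] += 1
    table = CountTable(
        cells={k: (v[0], v[1]) for k, v in cells.items()},
        total_records=len(records),
        include_history=include_history,
    )
    table.validate()
    return table


def _smoothed_ratio(death: int, occur: int, alpha: float) -> Optional[float]:
    denom = occur + 2.0 * alpha
    if denom == 0:
        return None
    return (death + alpha) / denom


def _transformed(raw: Optional[float], transform: str) -> Optional[float]:
    if raw is None:
        return None
    if transform == "raw":
        return raw
    if raw <= 0.0:
        return None  # log2(raw*10) undefined; cell stays absent
    return math.log2(raw * 10.0)


def compute_cdcp(
    counts: CountTable, transform: str = "raw", smoothing_alpha: float = 0.0
) -> CDCPTable:
    """Compute the CDCP table from a count table.

    Raw cell value: ``(death + α) / (occur + 2α)``.  Log cell value:
    ``log2(raw × 10)`` (bounded above by log2(10) ≈ 3.3219).  Cells with
    zero occurrences and α = 0 are absent rather than zero; under the
    log transform, cells whose raw ratio is zero are absent as well and
    a warning is logged.

    Pooled fallback cells (gender-pooled, age-pooled, global) are
    computed here from pooled counts.
    """
    if transform not in ("raw", "log"):
        raise ValueError(f"unknown transform: {transform!r}")
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be ≥ 0")
    table = CDCPTable(transform=transform, smoothing_alpha=smoothing_alpha)
    dropped = 0
    g_pool: Dict[Tuple[str, AgeGroup], list] = {}
    a_pool: Dict[Tuple[str, Gender], list] = {}
    glob: Dict[str, list] = {}
    for (code, ag, g), (occ, dth) in counts.cells.items():
        for pool, key in ((g_pool, (code, ag)), (a_pool, (code, g)), (glob, code)):
            cell = pool.setdefault(key, [0, 0])
            cell[0] += occ
            cell[1] += dth
        value = _transformed(_smoothed_ratio(dth, occ, smoothing_alpha), transform)
        if value is None:
            dropped += 1
            continue
        table.cells[(code, ag, g)] = value
    for pool, target in (
        (g_pool, table.gender_pooled),
        (a_pool, table.age_pooled),
        (glob, table.global_cells),
    ):
        for key, (occ, dth) in pool.items():
            value = _transformed(_smoothed_ratio(dth, occ, smoothing_alpha), transform)
            if value is not None:
                target[key] = value
    if dropped:
        logger.warning(
            "compute_cdcp: %d cells undefined under transform=%s, alpha=%g "
            "(left absent)",
            dropped,
            transform,
            smoothing_alpha,
        )
    return table


def compute_rdcp(records: Sequence[DeathRecord]) -> RDCPTable:
    """Fit the regional death cause proportion table.

    For region *j* and cause *i*: ``rdcp = n_ij / N_j`` where ``n_ij``
    counts deaths in region *j* whose underlying label is *i* and
    ``N_j`` is the total labeled deaths in region *j*.  Per-region
    values sum to one by construction.
    """
    require_labeled(records)
    counts: Dict[Tuple[str, str], int] = {}
    totals: Dict[str, int] = {}
    for r in records:
        totals[r.region] = totals.get(r.region, 0) + 1
        key = (r.region, r.underlying.code)
        counts[key] = counts.get(key, 0) + 1
    cells = {
        (region, code): n / totals[region] for (region, code), n in counts.items()
    }
    return RDCPTable(cells=cells, region_totals=totals)


def lookup_cdcp(
    table: CDCPTable,
    cause: Union[CauseCode, str],
    age_group: AgeGroup,
    gender: Gender,
    fallback_policy: str = "pooled",
) -> Optional[float]:
    """Look up a CDCP value, optionally falling back to pooled cells.

    Returns the exact stratum cell if present; under the ``pooled``
    policy an absent cell falls back to the gender-pooled cell, then the
    age-pooled cell, then the global cell; ``stratum`` / ``none`` stop
    at the exact cell.  ``None`` (absent) is a valid return.
    """
    if fallback_policy not in FALLBACK_POLICIES:
        raise ValueError(f"unknown fallback policy: {fallback_policy!r}")
    code = cause.code if isinstance(cause, CauseCode) else str(cause)
    value = table.cells.get((code, age_group, gender))
    if value is not None or fallback_policy in ("stratum", "none"):
        return value
    value = table.gender_pooled.get((code, age_group))
    if value is not None:
        return value
    value = table.age_pooled.get((code, gender))
    if value is not None:
        return value
    return table.global_cells.get(code)


# ---------------------------------------------------------------------------
# JSON serialization


def serialize_table(
    table: Union[CountTable, CDCPTable, RDCPTable], path: Union[str, Path]
) -> None:
    """Write a fitted table to JSON (round-trip stable, full double precision)."""
    if isinstance(table, CountTable):
        payload = {
            "version": _SERIAL_VERSION,
            "type": "counts",
            "include_history": table.include_history,
            "total_records": table.total_records,
            "cells": {
                _cell_key_str(*k): list(table.cells[k])
                for k in sorted(table.cells, key=lambda c: _cell_key_str(*c))
            },
        }
    elif isinstance(table, CDCPTable):
        payload = {
            "version": _SERIAL_VERSION,
            "type": "cdcp",
            "transform": table.transform,
            "smoothing_alpha": table.smoothing_alpha,
            "cells": {
                _cell_key_str(*k): table.cells[k]
                for k in sorted(table.cells, key=lambda c: _cell_key_str(*c))
            },
            "gender_pooled": {
                f"{code}|{ag.value}": table.gender_pooled[(code, ag)]
                for code, ag in sorted(
                    table.gender_pooled, key=lambda k: (k[0], k[1].value)
                )
            },
            "age_pooled": {
                f"{code}|{g.value}": table.age_pooled[(code, g)]
                for code, g in sorted(
                    table.age_pooled, key=lambda k: (k[0], k[1].value)
                )
            },
            "global_cells": dict(sorted(table.global_cells.items())),
        }
    elif isinstance(table, RDCPTable):
        payload = {
            "version": _SERIAL_VERSION,
            "type": "rdcp",
            "region_totals": dict(sorted(table.region_totals.items())),
            "cells": {
                f"{region}|{code}": v for (region, code), v in sorted(table.cells.items())
            },
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize {type(table).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def deserialize_table(
    path: Union[str, Path]
) -> Union[CountTable, CDCPTable, RDCPTable]:
    """Read a table written by :func:`serialize_table`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("version")
    if version != _SERIAL_VERSION:
        raise ValueError(f"unsupported table file version: {version!r}")
    kind = payload.get("type")
    if kind == "counts":
        return CountTable(
            cells={
                _parse_cell_key(k): (int(v[0]), int(v[1]))
                for k, v in payload["cells"].items()
            },
            total_records=int(payload["total_records"]),
            include_history=bool(payload["include_history"]),
        )
    if kind == "cdcp":
        table = CDCPTable(
            transform=payload["transform"],
            smoothing_alpha=float(payload["smoothing_alpha"]),
            cells={_parse_cell_key(k): float(v) for k, v in payload["cells"].items()},
        )
        for k, v in payload.get("gender_pooled", {}).items():
            code, ag = k.split("|")
            table.gender_pooled[(code, AgeGroup(ag))] = float(v)
        for k, v in payload.get("age_pooled", {}).items():
            code, g = k.split("|")
            table.age_pooled[(code, Gender(g))] = float(v)
        table.global_cells = {k: float(v) for k, v in payload.get("global_cells", {}).items()}
        return table
    if kind == "rdcp":
        cells = {}
        for k, v in payload["cells"].items():
            region, code = k.split("|")
            cells[(region, code)] = float(v)
        return RDCPTable(
            cells=cells,
            region_totals={k: int(v) for k, v in payload["region_totals"].items()},
        )
    raise ValueError(f"unknown table type: {kind!r}")
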