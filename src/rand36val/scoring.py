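"""RAND-36 item recoding and subscale scoring.

The RAND-36 health survey has 36 ordinal items on native 2- to 6-point
scales.  Each item is first recoded to 0-100 so that higher always means
better health, then eight subscales are formed by aggregating (by default
averaging) their member items.  Item 2 (Health change, "compared to one
year ago") is not part of any subscale; it is kept as an ordinal 5-point
category — reverse-recoded so higher = better — for paired ordinal
analysis.

The default missing-data policy is complete-case: a subscale is scored only
when every member item is answered.  The standard RAND "half rule" (score
when at least half the member items are answered) is available but not the
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RECODE_TABLE",
    "SUBSCALES",
    "ITEM_CHOICES",
    "Rand36Record",
    "SubscaleScores",
    "recode_item",
    "score_subscale",
    "score_all",
    "completeness_summary",
    "read_cohort_csv",
]


def _recode(groups: dict[tuple[int, ...], dict[int, int]]) -> dict[int, dict[int, int]]:
    table: dict[int, dict[int, int]] = {}
    for items, mapping in groups.items():
        for item in items:
            table[item] = dict(mapping)
    return table


#: Raw response -> 0-100 recode, per item (RAND standard scoring).  Shipped
#: as plain data so a scoring dialect can be swapped without code changes.
RECODE_TABLE: dict[int, dict[int, int]] = _recode(
    {
        (1, 2, 20, 22, 34, 36): {1: 100, 2: 75, 3: 50, 4: 25, 5: 0},
        tuple(range(3, 13)): {1: 0, 2: 50, 3: 100},
        tuple(range(13, 20)): {1: 0, 2: 100},
        (21, 23, 26, 27, 30): {1: 100, 2: 80, 3: 60, 4: 40, 5: 20, 6: 0},
        (24, 25, 28, 29, 31): {1: 0, 2: 20, 3: 40, 4: 60, 5: 80, 6: 100},
        (32, 33, 35): {1: 0, 2: 25, 3: 50, 4: 75, 5: 100},
    }
)

#: Subscale -> member items.
SUBSCALES: dict[str, tuple[int, ...]] = {
    "Physical functioning": tuple(range(3, 13)),
    "Role functioning/physical": (13, 14, 15, 16),
    "Pain": (21, 22),
    "General health": (1, 33, 34, 35, 36),
    "Energy/fatigue": (23, 27, 29, 31),
    "Social functioning": (20, 32),
    "Role functioning/emotional": (17, 18, 19),
    "Emotional well-being": (24, 25, 26, 28, 30),
}

HEALTH_CHANGE_ITEM = 2

#: Number of response choices per item, derived from the recode table.
ITEM_CHOICES: dict[int, int] = {item: len(m) for item, m in RECODE_TABLE.items()}

#: Items whose raw scale runs best-to-worst (recode decreasing in raw value).
ITEM_REVERSED: dict[int, bool] = {
    item: m[1] > m[max(m)] for item, m in RECODE_TABLE.items()
}


@dataclass(frozen=True)
class Rand36Record:
    """One questionnaire administration: 36 raw item responses plus keys."""

    patient_id: str
    group: str
    occasion: str
    date: date | None
    items: Mapping[int, int | None]

    def __post_init__(self) -> None:
        for item, raw in self.items.items():
            if item not in RECODE_TABLE:
                raise ValueError(f"unknown item number {item}")
            if raw is not None and raw not in RECODE_TABLE[item]:
                raise ValueError(
                    f"item {item}: raw response {raw} outside its "
                    f"{ITEM_CHOICES[item]}-point scale"
                )

    def response(self, item: int) -> int | None:
        return self.items.get(item)


@dataclass(frozen=True)
class SubscaleScores:
    """Eight 0-100 subscale scores plus the ordinal Health-change category."""

    scores: dict[str, float | None]
    health_change: int | None


def recode_item(item: int, raw: int) -> int:
    """Map a raw response to its 0-100 value (higher = better health)."""
    if item not in RECODE_TABLE:
        raise ValueError(f"unknown item number {item}")
    table = RECODE_TABLE[item]
    if raw not in table:
        raise ValueError(
            f"item {item}: raw response {raw!r} outside its {len(table)}-point scale"
        )
    return table[raw]


def _aggregate(values: list[float], aggregator: str) -> float:
    if aggregator == "mean":
        return float(np.mean(values))
    if aggregator == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregator {aggregator!r}")


def score_subscale(
    record: Rand36Record,
    subscale: str,
    aggregator: str = "mean",
    missing_policy: str = "complete_only",
) -> float | None:
    """Aggregate a record's recoded member items into one 0-100 score.

    ``complete_only`` (the default) returns None when any member item is
    missing; ``half_rule`` scores whenever at least half the member items
    are answered.
    """
    if subscale not in SUBSCALES:
        raise ValueError(f"unknown subscale {subscale!r}")
    if missing_policy not in ("complete_only", "half_rule"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    items = SUBSCALES[subscale]
    answered = [
        recode_item(item, record.response(item))
        for item in items
        if record.response(item) is not None
    ]
    if missing_policy == "complete_only":
        if len(answered) < len(items):
            return None
    else:
        if len(answered) < np.ceil(len(items) / 2):
            return None
    return _aggregate(answered, aggregator)


def health_change_category(record: Rand36Record) -> int | None:
    """Item 2 as an ordinal category with higher = better (1..5).

    The raw scale runs 1 = much better ... 5 = much worse, so the category
    is the reverse-recoded value ``6 - raw``.
    """
    raw = record.response(HEALTH_CHANGE_ITEM)
    if raw is None:
        return None
    return ITEM_CHOICES[HEALTH_CHANGE_ITEM] + 1 - raw


def score_all(
    record: Rand36Record,
    aggregator: str = "mean",
    missing_policy: str = "complete_only",
) -> SubscaleScores:
    """Score all eight subscales and extract the Health-change category."""
    scores = {
        name: score_subscale(record, name, aggregator, missing_policy)
        for name in SUBSCALES
    }
    return SubscaleScores(scores=scores, health_change=health_change_category(record))


def _pair_records(
    cohort: Iterable[Rand36Record],
) -> dict[str, dict[str, Rand36Record]]:
    by_patient: dict[str, dict[str, Rand36Record]] = {}
    for rec in cohort:
        occasions = by_patient.setdefault(rec.patient_id, {})
        if rec.occasion in occasions:
            raise ValueError(
                f"patient {rec.patient_id} has duplicate occasion {rec.occasion!r}"
            )
        occasions[rec.occasion] = rec
    return by_patient


def completeness_summary(cohort: Iterable[Rand36Record]) -> pd.DataFrame:
    """Per-subscale count (and percent) of patients complete at both occasions.

    A patient counts as complete for a subscale when no member item is
    missing in either of the two paired records.  Patients without exactly
    two occasions are excluded with a warning.
    """
    by_patient = _pair_records(cohort)
    paired = {pid: occ for pid, occ in by_patient.items() if len(occ) == 2}
    dropped = set(by_patient) - set(paired)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} unpaired patient(s): {sorted(dropped)}",
            stacklevel=2,
        )
    n = len(paired)
    rows = []
    targets = {**{name: items for name, items in SUBSCALES.items()},
               "Health change": (HEALTH_CHANGE_ITEM,)}
    for name, items in targets.items():
        complete = sum(
            all(
                rec.response(item) is not None
                for rec in occ.values()
                for item in items
            )
            for occ in paired.values()
        )
        rows.append(
            {
                "subscale": name,
                "n_items": len(items),
                "n_complete": complete,
                "percent_complete": 100.0 * complete / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# wide-CSV I/O (columns: patient_id, group, occasion, date, q1..q36)


def read_cohort_csv(path) -> list[Rand36Record]:
    """Read a wide cohort CSV into records (blank item cells = missing)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[Rand36Record]:
    """Convert a wide cohort table (one row per patient-occasion) to records."""
    required = {"patient_id", "group", "occasion", "date"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort table lacks columns: {sorted(missing_cols)}")
    records = []
    for _, row in df.iterrows():
        items: dict[int, int | None] = {}
        for item in RECODE_TABLE:
            raw = row.get(f"q{item}")
            items[item] = None if pd.isna(raw) else int(raw)
        when = row["date"]
        when = None if pd.isna(when) else pd.Timestamp(when).date()
        records.append(
            Rand36Record(
                patient_id=str(row["patient_id"]),
                group=str(row["group"]),
                occasion=str(row["occasion"]),
                date=when,
                items=items,
            )
        )
    return records
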