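"""Instrument structure and scoring for a 14-item daily COPD symptom diary.

The instrument has 14 ordinal items recorded once per day. Nine items are
scored 0-4 and five are scored 0-3. Eleven of the items form a respiratory
symptom subset scored by plain summation (0-40) with three subscales
(breathlessness 0-17, cough & sputum 0-11, chest symptoms 0-12). The full
14-item total is reported on a 0-100 interval scale obtained by mapping the
raw 14-item sum (0-51) through a score-to-measure table (:class:`ScoreMap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemDefinition",
    "ITEM_BANK_STRUCTURE",
    "ERS_ITEMS",
    "SUBSCALE_ITEMS",
    "MAX_RAW_SUM",
    "DiaryRecord",
    "DiaryDataset",
    "ScoreMap",
    "rs_total",
    "subscale_totals",
    "exact_total",
    "score_dataset",
    "read_diary_csv",
    "write_diary_csv",
]

N_ITEMS = 14

SUBSCALE_ITEMS: dict[str, tuple[int, ...]] = {
    "breathlessness": (7, 8, 9, 10, 11),
    "cough_sputum": (2, 3, 4),
    "chest_symptoms": (1, 5, 6),
}

ERS_ITEMS: tuple[int, ...] = tuple(range(1, 12))

SUBSCALE_MAXIMA = {"breathlessness": 17, "cough_sputum": 11, "chest_symptoms": 12}


@dataclass(frozen=True)
class ItemDefinition:
    """One diary item: identity, construct label and response range."""

    item_id: int
    construct: str
    max_score: int
    in_ers: bool
    subscale: str

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= N_ITEMS:
            raise ValueError(f"item_id must be in 1..{N_ITEMS}, got {self.item_id}")
        if self.max_score not in (3, 4):
            raise ValueError(f"max_score must be 3 or 4, got {self.max_score}")


def _build_structure() -> tuple[ItemDefinition, ...]:
    rows = [
        (1, "Congestion", 4, "chest_symptoms"),
        (2, "Cough frequency", 4, "cough_sputum"),
        (3, "Mucus quantity", 3, "cough_sputum"),
        (4, "Difficulty with mucus", 4, "cough_sputum"),
        (5, "Discomfort", 4, "chest_symptoms"),
        (6, "Tightness", 4, "chest_symptoms"),
        (7, "Breathless today", 4, "breathlessness"),
        (8, "Breathless with activity", 3, "breathlessness"),
        (9, "Short of breath - personal care", 4, "breathlessness"),
        (10, "Short of breath - indoor activities", 3, "breathlessness"),
        (11, "Short of breath - outdoor activities", 3, "breathlessness"),
        (12, "Tired or weak", 4, "none"),
        (13, "Sleep disturbance", 4, "none"),
        (14, "Scared or worried", 3, "none"),
    ]
    return tuple(
        ItemDefinition(
            item_id=i,
            construct=c,
            max_score=m,
            in_ers=i in ERS_ITEMS,
            subscale=s if i in ERS_ITEMS else ("additional" if s == "none" else s),
        )
        for i, c, m, s in rows
    )


ITEM_BANK_STRUCTURE: tuple[ItemDefinition, ...] = _build_structure()

ITEM_MAX_SCORE: dict[int, int] = {d.item_id: d.max_score for d in ITEM_BANK_STRUCTURE}

#: Maximum possible raw 14-item sum (nine items 0-4, five items 0-3).
MAX_RAW_SUM: int = sum(ITEM_MAX_SCORE.values())

ARMS = ("drug", "placebo")


class MissingDayError(ValueError):
    """Raised when a scoring function receives a missing or incomplete day."""


def _validate_complete(responses: Mapping[int, int]) -> None:
    if responses is None:
        raise MissingDayError("cannot score missing day")
    missing = set(ITEM_MAX_SCORE) - set(responses)
    if missing:
        raise MissingDayError(f"cannot score missing day: items {sorted(missing)} absent")
    for item_id, score in responses.items():
        if item_id not in ITEM_MAX_SCORE:
            raise ValueError(f"unknown item_id {item_id}")
        if not 0 <= int(score) <= ITEM_MAX_SCORE[item_id]:
            raise ValueError(
                f"item {item_id} score {score} out of range 0..{ITEM_MAX_SCORE[item_id]}"
            )


def rs_total(responses: Mapping[int, int]) -> int:
    """Sum of the 11 respiratory-symptom items (0-40)."""
    _validate_complete(responses)
    return int(sum(responses[i] for i in ERS_ITEMS))


def subscale_totals(responses: Mapping[int, int]) -> dict[str, int]:
    """Breathlessness (0-17), cough & sputum (0-11), chest symptoms (0-12)."""
    _validate_complete(responses)
    return {
        name: int(sum(responses[i] for i in items))
        for name, items in SUBSCALE_ITEMS.items()
    }


@dataclass(frozen=True)
class ScoreMap:
    """Lookup table mapping the raw 14-item sum (0..51) onto a 0-100 scale.

    The official instrument uses a proprietary logit score-to-measure table;
    a structurally equivalent default can be generated from fitted item
    parameters (see :func:`proirm.irt_core.default_score_map`). Values must
    be monotone non-decreasing with anchors 0 at sum 0 and 100 at the
    maximum sum.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (MAX_RAW_SUM + 1,):
            raise ValueError(
                f"score map must have {MAX_RAW_SUM + 1} entries, got {v.shape}"
            )
        if np.any(np.diff(v) < 0):
            raise ValueError("score map must be monotone non-decreasing")
        if not (abs(v[0]) < 1e-9 and abs(v[-1] - 100.0) < 1e-9):
            raise ValueError("score map must anchor 0 -> 0 and max sum -> 100")

    def __call__(self, raw_sum: int) -> float:
        if not 0 <= raw_sum <= MAX_RAW_SUM:
            raise ValueError(f"raw sum {raw_sum} outside 0..{MAX_RAW_SUM}")
        return float(self.values[raw_sum])

    @classmethod
    def linear(cls) -> "ScoreMap":
        """Fallback map: linear rescaling of the raw sum."""
        return cls(tuple(100.0 * s / MAX_RAW_SUM for s in range(MAX_RAW_SUM + 1)))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ScoreMap":
        df = pd.read_csv(path)
        if not {"raw_sum", "measure_0_100"} <= set(df.columns):
            raise ValueError("score map CSV needs columns raw_sum, measure_0_100")
        df = df.sort_values("raw_sum")
        if list(df["raw_sum"]) != list(range(MAX_RAW_SUM + 1)):
            raise ValueError(f"score map CSV must cover raw sums 0..{MAX_RAW_SUM}")
        return cls(tuple(float(x) for x in df["measure_0_100"]))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"raw_sum": range(MAX_RAW_SUM + 1), "measure_0_100": self.values}
        ).to_csv(path, index=False)


def exact_total(responses: Mapping[int, int], score_map: ScoreMap) -> float:
    """14-item total on the 0-100 scale via the score-to-measure table."""
    _validate_complete(responses)
    raw = int(sum(responses[i] for i in ITEM_MAX_SCORE))
    return score_map(raw)


@dataclass(frozen=True)
class DiaryRecord:
    """One subject-day. ``responses`` is None for a whole missing day."""

    subject_id: str
    arm: str
    day: int
    responses: Mapping[int, int] | None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.responses is not None:
            _validate_complete(self.responses)

    @property
    def is_missing(self) -> bool:
        return self.responses is None


@dataclass
class DiaryDataset:
    """Long-format diary data: one complete 14-item record per subject-day.

    Missing days are represented by absence; subject arm membership is kept
    in per-subject metadata so fully missing tails remain attributable.
    """

    records: list[DiaryRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        arms: dict[str, str] = {}
        for rec in self.records:
            key = (rec.subject_id, rec.day)
            if key in seen:
                raise ValueError(f"duplicate (subject, day) pair {key}")
            seen.add(key)
            prev = arms.setdefault(rec.subject_id, rec.arm)
            if prev != rec.arm:
                raise ValueError(f"subject {rec.subject_id} has inconsistent arm labels")

    @property
    def present(self) -> list[DiaryRecord]:
        return [r for r in self.records if not r.is_missing]

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.subject_id not in seen:
                seen.add(r.subject_id)
                out.append(r.subject_id)
        return out

    def arm_of(self, subject_id: str) -> str:
        for r in self.records:
            if r.subject_id == subject_id:
                return r.arm
        raise KeyError(subject_id)

    def subject_records(self, subject_id: str) -> list[DiaryRecord]:
        recs = [r for r in self.records if r.subject_id == subject_id]
        return sorted(recs, key=lambda r: r.day)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (present days only): subject_id, arm, day, item_id, score."""
        rows = []
        for rec in self.records:
            if rec.is_missing:
                continue
            for item_id in sorted(ITEM_MAX_SCORE):
                rows.append((rec.subject_id, rec.arm, rec.day, item_id, rec.responses[item_id]))
        return pd.DataFrame(rows, columns=["subject_id", "arm", "day", "item_id", "score"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiaryDataset":
        required = {"subject_id", "arm", "day", "item_id", "score"}
        if not required <= set(df.columns):
            raise ValueError(f"diary frame needs columns {sorted(required)}")
        records = []
        for (subject_id, arm, day), grp in df.groupby(
            ["subject_id", "arm", "day"], sort=True
        ):
            if len(grp) != N_ITEMS or set(grp["item_id"]) != set(ITEM_MAX_SCORE):
                raise ValueError(
                    f"partial day: subject {subject_id} day {day} has "
                    f"{len(grp)} item rows (need all {N_ITEMS})"
                )
            for _, row in grp.iterrows():
                mx = ITEM_MAX_SCORE[int(row["item_id"])]
                if not 0 <= int(row["score"]) <= mx:
                    raise ValueError(
                        f"score out of range in row (subject {subject_id}, day {day}, "
                        f"item {int(row['item_id'])}): {int(row['score'])} > max {mx}"
                    )
            responses = {int(r["item_id"]): int(r["score"]) for _, r in grp.iterrows()}
            records.append(
                DiaryRecord(str(subject_id), str(arm), int(day), responses)
            )
        return cls(records=records)


def score_dataset(
    dataset: DiaryDataset, score_map: ScoreMap | None = None
) -> pd.DataFrame:
    """Per present subject-day scores on all five reported scales.

    Returns a frame with columns subject_id, arm, day, rs_total, exact_total,
    breathlessness, cough_sputum, chest_symptoms. Pure: the dataset is not
    modified.
    """
    score_map = score_map or ScoreMap.linear()
    rows = []
    for rec in dataset.records:
        if rec.is_missing:
            continue
        subs = subscale_totals(rec.responses)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "arm": rec.arm,
                "day": rec.day,
                "rs_total": rs_total(rec.responses),
                "exact_total": exact_total(rec.responses, score_map),
                **subs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "arm",
            "day",
            "rs_total",
            "exact_total",
            "breathlessness",
            "cough_sputum",
            "chest_symptoms",
        ],
    )


def read_diary_csv(path: str | Path) -> DiaryDataset:
    """Read a long-format diary CSV (subject_id, arm, day, item_id, score)."""
    df = pd.read_csv(path)
    return DiaryDataset.from_frame(df)


def write_diary_csv(dataset: DiaryDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)
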