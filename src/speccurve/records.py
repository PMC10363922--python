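"""Participant-level data container and conversions.

A cohort is a list of :class:`ParticipantRecord`, one per person: group
membership (neurologically healthy adult vs. stroke survivor), the two
covariates used throughout (age and years of education), and the raw task
observations from which every outcome metric is derived.  A raw field that
was not observed is simply absent from ``raw`` (missing-at-record level);
in tabular form missing values are NaN / empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

import numpy as np
import pandas as pd

GROUPS = ("healthy", "stroke")

#: Columns that precede the raw task fields in the canonical wide CSV.
ID_COLUMNS = ("id", "group", "age", "education")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: identity, group, covariates, raw observations."""

    id: str
    group: str
    age: float | None
    education: float | None
    raw: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )
        for name, value in (("age", self.age), ("education", self.education)):
            if value is not None and value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")


def records_to_frame(records: Iterable[ParticipantRecord],
                     raw_fields: Iterable[str]) -> pd.DataFrame:
    """Wide DataFrame: id, group, age, education, then one raw column each.

    Missing raw fields (and missing covariates) become NaN.
    """
    raw_fields = list(raw_fields)
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "group": rec.group,
            "age": np.nan if rec.age is None else rec.age,
            "education": np.nan if rec.education is None else rec.education,
        }
        for f in raw_fields:
            row[f] = rec.raw.get(f, np.nan)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(ID_COLUMNS) + raw_fields)
    return frame


def frame_to_records(frame: pd.DataFrame,
                     raw_fields: Iterable[str]) -> list[ParticipantRecord]:
    """Inverse of :func:`records_to_frame`; NaN cells become absent fields."""
    records = []
    for _, row in frame.iterrows():
        raw = {}
        for f in raw_fields:
            v = row[f]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                raw[f] = float(v)
        age = row["age"]
        edu = row["education"]
        records.append(ParticipantRecord(
            id=str(row["id"]),
            group=str(row["group"]),
            age=None if pd.isna(age) else float(age),
            education=None if pd.isna(edu) else float(edu),
            raw=raw,
        ))
    return records
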