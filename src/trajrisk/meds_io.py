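"""Event-level EHR table I/O in the MEDS convention.

MEDS (Medical Event Data Standard) represents an EHR as one row per
clinical event with four columns -- ``subject_id``, ``time``, ``code``,
``numeric_value`` -- plus a separate static-demographics table keyed by
``subject_id``.  This module reads and writes both tables (CSV text or
Parquet columnar), validates rows, and groups events chronologically per
subject.  Timestamps are stored at minute resolution (sub-minute precision
is irrelevant downstream because gaps under five minutes emit no token).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["subject_id", "time", "code", "numeric_value"]
STATIC_COLUMNS = ["subject_id", "gender", "marital_status", "race", "bmi", "age_at_start"]

#: Category value used for missing categorical statics.
UNKNOWN = "unknown"


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong type."""


@dataclass(frozen=True)
class EventRecord:
    """One clinical event row.

    ``code`` carries a scheme prefix (``ICD10CM/``, ``ICD10PCS/``, ``ATC/``,
    ``LAB/``, ``VITAL/`` or a special-event scheme such as ``ADMIT/``).
    ``numeric_value`` is present only for numeric code classes (labs, vitals).
    """

    subject_id: str
    time: datetime
    code: str
    numeric_value: float | None = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")
        if self.time.tzinfo is None:
            object.__setattr__(self, "time", self.time.replace(tzinfo=timezone.utc))
        # minute resolution by truncation
        object.__setattr__(
            self, "time", self.time.replace(second=0, microsecond=0)
        )


@dataclass(frozen=True)
class SubjectStatics:
    """Per-subject demographic attributes known at timeline start."""

    subject_id: str
    gender: str = UNKNOWN
    marital_status: str = UNKNOWN
    race: str = UNKNOWN
    bmi: float | None = None
    age_at_start: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.age_at_start <= 99:
            raise ValueError(f"age_at_start must be in [0, 99], got {self.age_at_start}")


@dataclass
class ReadReport:
    """Row-level validation outcome of a read."""

    n_rows: int = 0
    n_rejected: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)  # (row number, reason)


def _parse_time(value) -> datetime | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, datetime):
        ts = value
    else:
        s = str(value).strip()
        if not s or s.lower() in ("nan", "nat"):
            return None
        try:
            ts = datetime.fromisoformat(s)
        except ValueError:
            return None
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).replace(second=0, microsecond=0)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path, dtype={"subject_id": str, "code": str})


def read_events(path: str | Path) -> tuple[dict[str, list[EventRecord]], ReadReport]:
    """Read a MEDS event table, grouped by subject and sorted chronologically.

    Ties on (subject, minute) keep stable input order so tokenization is
    reproducible.  Malformed rows (blank/unparseable time, empty code) are
    rejected and reported with their 0-based row numbers.
    """
    df = _read_table(path)
    missing = [c for c in ("subject_id", "time", "code") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    if "numeric_value" not in df.columns:
        df = df.assign(numeric_value=np.nan)

    report = ReadReport(n_rows=len(df))
    rows: list[tuple[str, datetime, int, EventRecord]] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        code = "" if rec.code is None or (isinstance(rec.code, float)) else str(rec.code)
        ts = _parse_time(rec.time)
        if ts is None:
            report.n_rejected += 1
            report.rejected_rows.append((i, "unparseable or blank time"))
            continue
        if not code or code == "nan":
            report.n_rejected += 1
            report.rejected_rows.append((i, "empty code"))
            continue
        val = rec.numeric_value
        val = None if val is None or (isinstance(val, float) and np.isnan(val)) else float(val)
        rows.append((str(rec.subject_id), ts, i, EventRecord(str(rec.subject_id), ts, code, val)))

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    grouped: dict[str, list[EventRecord]] = {}
    for sid, _, _, record in rows:
        grouped.setdefault(sid, []).append(record)
    return grouped, report


def write_events(
    records: Iterable[EventRecord] | Mapping[str, list[EventRecord]],
    path: str | Path,
) -> None:
    """Write events sorted by (subject, time, input order); dialect from suffix."""
    if isinstance(records, Mapping):
        flat = [r for sid in records for r in records[sid]]
    else:
        flat = list(records)
    indexed = sorted(enumerate(flat), key=lambda ir: (ir[1].subject_id, ir[1].time, ir[0]))
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for _, r in indexed],
            "time": [r.time.strftime("%Y-%m-%dT%H:%M:%S") for _, r in indexed],
            "code": [r.code for _, r in indexed],
            "numeric_value": [r.numeric_value for _, r in indexed],
        }
    )
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_statics(path: str | Path) -> dict[str, SubjectStatics]:
    """Read the static-demographics table; missing categoricals become 'unknown'."""
    df = _read_table(path)
    if "subject_id" not in df.columns or "age_at_start" not in df.columns:
        raise SchemaError("statics table requires subject_id and age_at_start columns")
    out: dict[str, SubjectStatics] = {}
    for rec in df.itertuples(index=False):
        sid = str(rec.subject_id)

        def cat(name: str) -> str:
            v = getattr(rec, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "nan":
                return UNKNOWN
            return str(v)

        bmi = getattr(rec, "bmi", None)
        bmi = None if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)) else float(bmi)
        out[sid] = SubjectStatics(
            subject_id=sid,
            gender=cat("gender"),
            marital_status=cat("marital_status"),
            race=cat("race"),
            bmi=bmi,
            age_at_start=int(rec.age_at_start),
        )
    return out


def write_statics(statics: Iterable[SubjectStatics], path: str | Path) -> None:
    rows = sorted(statics, key=lambda s: s.subject_id)
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in rows],
            "gender": [s.gender for s in rows],
            "marital_status": [s.marital_status for s in rows],
            "race": [s.race for s in rows],
            "bmi": [s.bmi for s in rows],
            "age_at_start": [s.age_at_start for s in rows],
        }
    )
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
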