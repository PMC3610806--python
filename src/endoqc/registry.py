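"""Persistent store of bench measurements, keyed by endoscope serial and type.

Backed by a single SQLite file (or ``:memory:``) with a flat schema, plus a
CSV dialect for diff-able import/export:

    serial,type_id,timestamp,transmission,contrast,moisture,context

Timestamps are ISO-8601; ``(serial, timestamp)`` is unique. The best-of-type
baseline is the per-metric historical maximum over every stored record of
that type, so it is monotone non-decreasing as records are appended.
"""

from __future__ import annotations

import csv
import enum
import sqlite3
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

from .errors import ConflictError, NoBaselineError, ValidationError

__all__ = [
    "Context",
    "Metric",
    "MeasurementRecord",
    "Registry",
    "CSV_HEADER",
]

CSV_HEADER = [
    "serial",
    "type_id",
    "timestamp",
    "transmission",
    "contrast",
    "moisture",
    "context",
]


class Context(str, enum.Enum):
    CLINICAL = "CLINICAL"
    NEW = "NEW"
    BEFORE_REPAIR = "BEFORE_REPAIR"
    AFTER_REPAIR = "AFTER_REPAIR"
    REFERENCE = "REFERENCE"


class Metric(str, enum.Enum):
    TRANSMISSION = "TRANSMISSION"
    CONTRAST = "CONTRAST"

    @property
    def column(self) -> str:
        return self.value.lower()


@dataclass(frozen=True)
class MeasurementRecord:
    """One bench session's outcome for one endoscope."""

    serial: str
    type_id: str
    timestamp: datetime
    transmission: float  # units, 0-100 scale (may slightly exceed 100 under noise)
    contrast: float  # grey levels, 0-255
    moisture: bool = False
    context: Context = Context.CLINICAL

    def __post_init__(self) -> None:
        if not self.serial:
            raise ValidationError("serial must be non-empty")
        if not self.type_id:
            raise ValidationError("type_id must be non-empty")
        if not isinstance(self.timestamp, datetime):
            raise ValidationError("timestamp must be a datetime")
        if self.transmission < 0:
            raise ValidationError(f"transmission must be >= 0, got {self.transmission}")
        if not 0 <= self.contrast <= 255:
            raise ValidationError(f"contrast must be in [0, 255], got {self.contrast}")
        if not isinstance(self.context, Context):
            object.__setattr__(self, "context", Context(self.context))

    def value(self, metric: Metric) -> float:
        return self.transmission if metric is Metric.TRANSMISSION else self.contrast

    def to_row(self) -> list[str]:
        return [
            self.serial,
            self.type_id,
            self.timestamp.isoformat(),
            repr(float(self.transmission)),
            repr(float(self.contrast)),
            "1" if self.moisture else "0",
            self.context.value,
        ]

    @classmethod
    def from_row(cls, row: dict[str, str]) -> "MeasurementRecord":
        return cls(
            serial=row["serial"],
            type_id=row["type_id"],
            timestamp=datetime.fromisoformat(row["timestamp"]),
            transmission=float(row["transmission"]),
            contrast=float(row["contrast"]),
            moisture=row["moisture"] in ("1", "true", "True"),
            context=Context(row["context"]),
        )

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "serial": self.serial,
            "type_id": self.type_id,
            "timestamp": self.timestamp.isoformat(),
            "transmission": float(self.transmission),
            "contrast": float(self.contrast),
            "moisture": bool(self.moisture),
            "context": self.context.value,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "MeasurementRecord":
        return cls(
            serial=data["serial"],
            type_id=data["type_id"],
            timestamp=datetime.fromisoformat(data["timestamp"]),
            transmission=float(data["transmission"]),
            contrast=float(data["contrast"]),
            moisture=bool(data["moisture"]),
            context=Context(data["context"]),
        )


_SCHEMA = """
CREATE TABLE IF NOT EXISTS measurements (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    serial TEXT NOT NULL,
    type_id TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    transmission REAL NOT NULL,
    contrast REAL NOT NULL,
    moisture INTEGER NOT NULL,
    context TEXT NOT NULL,
    UNIQUE (serial, timestamp)
);
CREATE INDEX IF NOT EXISTS idx_measurements_type ON measurements (type_id);
CREATE INDEX IF NOT EXISTS idx_measurements_serial ON measurements (serial);
"""


class Registry:
    """SQLite-backed measurement database.

    Parameters
    ----------
    path:
        Database file path, or ``":memory:"`` for an ephemeral store.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Registry":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writes ------------------------------------------------------------

    def add_record(self, record: MeasurementRecord) -> int:
        """Persist one record; duplicate (serial, timestamp) is a conflict."""
        try:
            cur = self._conn.execute(
                "INSERT INTO measurements "
                "(serial, type_id, timestamp, transmission, contrast, moisture, context) "
                "VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    record.serial,
                    record.type_id,
                    record.timestamp.isoformat(),
                    float(record.transmission),
                    float(record.contrast),
                    int(record.moisture),
                    record.context.value,
                ),
            )
        except sqlite3.IntegrityError as exc:
            raise ConflictError(
                f"record for ({record.serial}, {record.timestamp.isoformat()}) "
                "already stored"
            ) from exc
        self._conn.commit()
        return int(cur.lastrowid)

    # -- queries -----------------------------------------------------------

    @staticmethod
    def _to_record(row: tuple) -> MeasurementRecord:
        serial, type_id, ts, transmission, contrast, moisture, context = row
        return MeasurementRecord(
            serial=serial,
            type_id=type_id,
            timestamp=datetime.fromisoformat(ts),
            transmission=transmission,
            contrast=contrast,
            moisture=bool(moisture),
            context=Context(context),
        )

    _SELECT = (
        "SELECT serial, type_id, timestamp, transmission, contrast, moisture, context "
        "FROM measurements"
    )

    def query_by_serial(
        self, serial: str, context: Context | None = None
    ) -> list[MeasurementRecord]:
        """All records for one endoscope, ascending by timestamp."""
        sql = self._SELECT + " WHERE serial = ?"
        params: list = [serial]
        if context is not None:
            sql += " AND context = ?"
            params.append(context.value)
        sql += " ORDER BY timestamp ASC"
        return [self._to_record(r) for r in self._conn.execute(sql, params)]

    def query_by_type(self, type_id: str) -> list[MeasurementRecord]:
        sql = self._SELECT + " WHERE type_id = ? ORDER BY timestamp ASC, serial ASC"
        return [self._to_record(r) for r in self._conn.execute(sql, [type_id])]

    def all_records(self) -> list[MeasurementRecord]:
        sql = self._SELECT + " ORDER BY timestamp ASC, serial ASC"
        return [self._to_record(r) for r in self._conn.execute(sql)]

    def serials(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT DISTINCT serial FROM measurements ORDER BY serial"
        )
        return [r[0] for r in rows]

    def best_of_type(self, type_id: str, metric: Metric) -> float:
        """Historical maximum of one metric over all records of a type."""
        row = self._conn.execute(
            f"SELECT MAX({metric.column}) FROM measurements WHERE type_id = ?",
            [type_id],
        ).fetchone()
        if row is None or row[0] is None:
            raise NoBaselineError(f"no records stored for type {type_id!r}")
        return float(row[0])

    def bests_of_type(self, type_id: str) -> dict[Metric, float]:
        return {m: self.best_of_type(type_id, m) for m in Metric}

    # -- CSV ---------------------------------------------------------------

    def export_csv(self, path: str | Path) -> int:
        """Write all records as CSV; returns the number of rows written."""
        records = self.all_records()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for rec in records:
                writer.writerow(rec.to_row())
        return len(records)

    def import_csv(self, path: str | Path) -> int:
        """Load records from CSV; returns the number of rows imported."""
        n = 0
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                self.add_record(MeasurementRecord.from_row(row))
                n += 1
        return n


def with_context(record: MeasurementRecord, context: Context) -> MeasurementRecord:
    """Copy of *record* with a different context tag."""
    return replace(record, context=context)
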