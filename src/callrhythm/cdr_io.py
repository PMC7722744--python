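"""Reading, validation and period assignment of call detail records (CDRs).

A CDR event log is a delimited text file with one telephone event per row:
the owner of the line, a timestamp, the call direction (outgoing or
incoming), optionally the peer identifier and the call duration in seconds.
The column layout and the tokens used to encode direction vary between
providers, so both are configurable through a :class:`Dialect`.

The analysis pipeline coarse-grains the observation window into ``N_T``
successive time periods (:class:`TimePartition`, half-open intervals) and
optionally restricts the events to one call direction before the hourly
rhythm is computed.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "Mode",
    "CallRecord",
    "Dialect",
    "DEFAULT_DIALECT",
    "TimePartition",
    "ConfigurationError",
    "InputError",
    "read_cdr",
    "write_cdr",
    "assign_periods",
    "select_direction",
    "period_summary",
]


class ConfigurationError(ValueError):
    """A dialect or analysis configuration is inconsistent or incomplete."""


class InputError(ValueError):
    """A data row cannot be parsed under strict parsing."""


class Direction(str, enum.Enum):
    """Direction of a single call as recorded by the provider."""

    OUTGOING = "outgoing"
    INCOMING = "incoming"


class Mode(str, enum.Enum):
    """Direction filter applied to an analysis: outgoing, incoming or total."""

    OUTGOING = "outgoing"
    INCOMING = "incoming"
    TOTAL = "total"


@dataclass(frozen=True)
class CallRecord:
    """One telephone event.

    Parameters
    ----------
    owner_id:
        Opaque identifier of the line owner (the focal individual).
    timestamp:
        Local civil date-time of the call; minute precision is sufficient.
        Timestamps are taken as recorded — no time-zone or DST
        normalisation is applied.
    direction:
        Whether the owner placed (outgoing) or received (incoming) the call.
    peer_id:
        Opaque identifier of the other party; may be absent.
    duration_s:
        Call duration in seconds; non-negative when present.  The rhythm
        analysis ignores durations (the event itself is the observation).
    """

    owner_id: str
    timestamp: datetime
    direction: Direction
    peer_id: str | None = None
    duration_s: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s is not None and self.duration_s < 0:
            raise ValueError(f"duration_s must be >= 0, got {self.duration_s}")


# Default column layout: a header row naming the five canonical fields,
# ISO-8601 timestamps, and direction spelled out in full.
@dataclass(frozen=True)
class Dialect:
    """Column mapping and token decoding for a CDR file.

    ``columns`` maps CallRecord field names to header names in the file;
    ``direction_tokens`` maps the file's direction tokens (lower-cased) to
    :class:`Direction` values.  ``timestamp_format`` is a
    ``datetime.strptime`` format, or ``None`` for ISO-8601.
    """

    separator: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "owner_id": "owner_id",
            "timestamp": "timestamp",
            "direction": "direction",
            "peer_id": "peer_id",
            "duration_s": "duration_s",
        }
    )
    direction_tokens: Mapping[str, Direction] = field(
        default_factory=lambda: {
            "outgoing": Direction.OUTGOING,
            "incoming": Direction.INCOMING,
        }
    )
    timestamp_format: str | None = None

    def __post_init__(self) -> None:
        for required in ("owner_id", "timestamp", "direction"):
            if required not in self.columns:
                raise ConfigurationError(f"dialect lacks a column for '{required}'")
        if not self.direction_tokens:
            raise ConfigurationError("dialect defines no direction tokens")

    def parse_timestamp(self, token: str) -> datetime:
        if self.timestamp_format is None:
            return datetime.fromisoformat(token.strip())
        return datetime.strptime(token.strip(), self.timestamp_format)

    def parse_direction(self, token: str) -> Direction:
        try:
            return self.direction_tokens[token.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown direction token {token!r}") from None


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class TimePartition:
    """An ordered partition of the observation window into ``N_T`` periods.

    Periods are half-open intervals ``[start_k, end_k)`` in local time with
    labels ``T1 … T{N_T}`` by default; they must be contiguous,
    non-overlapping and strictly increasing.
    """

    starts: tuple[datetime, ...]
    ends: tuple[datetime, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (n == len(self.ends) == len(self.labels)):
            raise ConfigurationError("starts, ends and labels must have equal length")
        if n < 2:
            raise ConfigurationError(f"a partition needs at least 2 periods, got {n}")
        if len(set(self.labels)) != n:
            raise ConfigurationError("period labels must be unique")
        for k in range(n):
            if self.ends[k] <= self.starts[k]:
                raise ConfigurationError(f"period {self.labels[k]} is empty or inverted")
            if k and self.starts[k] < self.ends[k - 1]:
                raise ConfigurationError("periods overlap or are out of order")

    @property
    def n_periods(self) -> int:
        return len(self.labels)

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[tuple[datetime, datetime]],
        labels: Sequence[str] | None = None,
    ) -> "TimePartition":
        if labels is None:
            labels = [f"T{k + 1}" for k in range(len(intervals))]
        starts, ends = zip(*intervals) if intervals else ((), ())
        return cls(tuple(starts), tuple(ends), tuple(labels))

    @classmethod
    def equal_split(
        cls, start: datetime, end: datetime, n_periods: int
    ) -> "TimePartition":
        """Split ``[start, end)`` into ``n_periods`` equal half-open periods."""
        if n_periods < 2:
            raise ConfigurationError("n_periods must be >= 2")
        if end <= start:
            raise ConfigurationError("observation window is empty")
        step = (end - start) / n_periods
        intervals = [(start + k * step, start + (k + 1) * step) for k in range(n_periods)]
        # close the last interval exactly at `end` to avoid rounding residue
        intervals[-1] = (intervals[-1][0], end)
        return cls.from_intervals(intervals)

    def locate(self, timestamp: datetime) -> str | None:
        """Label of the period containing ``timestamp``, or ``None``."""
        for k in range(self.n_periods):
            if self.starts[k] <= timestamp < self.ends[k]:
                return self.labels[k]
        return None


def read_cdr(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    strict: bool = False,
) -> list[CallRecord]:
    """Read a CDR event log.

    Malformed rows are skipped with a warning by default; under
    ``strict=True`` the first bad row raises :class:`InputError` naming the
    row number.  A missing mandatory column raises
    :class:`ConfigurationError` regardless of mode.
    """
    path = Path(path)
    records: list[CallRecord] = []
    skipped = 0
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.separator)
        header = reader.fieldnames or []
        for fieldname in ("owner_id", "timestamp", "direction"):
            if dialect.columns[fieldname] not in header:
                raise ConfigurationError(
                    f"column '{dialect.columns[fieldname]}' (for {fieldname}) "
                    f"not found in header of {path}"
                )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, dialect))
            except (ValueError, KeyError) as exc:
                if strict:
                    raise InputError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
                log.warning("skipping malformed row %s:%d: %s", path, lineno, exc)
    if skipped:
        log.warning("read_cdr: skipped %d malformed row(s) in %s", skipped, path)
    return records


def _parse_row(row: Mapping[str, str], dialect: Dialect) -> CallRecord:
    cols = dialect.columns
    peer_col = cols.get("peer_id")
    dur_col = cols.get("duration_s")
    peer = row.get(peer_col) if peer_col else None
    dur_token = row.get(dur_col) if dur_col else None
    duration = int(dur_token) if dur_token not in (None, "") else None
    return CallRecord(
        owner_id=row[cols["owner_id"]].strip(),
        timestamp=dialect.parse_timestamp(row[cols["timestamp"]]),
        direction=dialect.parse_direction(row[cols["direction"]]),
        peer_id=(peer.strip() or None) if peer is not None else None,
        duration_s=duration,
    )


def write_cdr(
    records: Iterable[CallRecord],
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
) -> None:
    """Write records back out in the same dialect (round-trip companion)."""
    cols = dialect.columns
    reverse_tokens = {d: tok for tok, d in dialect.direction_tokens.items()}
    fieldnames = [cols[f] for f in ("owner_id", "timestamp", "direction", "peer_id", "duration_s") if f in cols]
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter=dialect.separator)
        writer.writeheader()
        for rec in records:
            ts = (
                rec.timestamp.isoformat(sep=" ")
                if dialect.timestamp_format is None
                else rec.timestamp.strftime(dialect.timestamp_format)
            )
            row = {
                cols["owner_id"]: rec.owner_id,
                cols["timestamp"]: ts,
                cols["direction"]: reverse_tokens[rec.direction],
            }
            if "peer_id" in cols:
                row[cols["peer_id"]] = rec.peer_id or ""
            if "duration_s" in cols:
                row[cols["duration_s"]] = "" if rec.duration_s is None else rec.duration_s
            writer.writerow(row)


def assign_periods(
    records: Iterable[CallRecord], partition: TimePartition
) -> tuple[dict[str, list[CallRecord]], list[CallRecord]]:
    """Assign each record to the period containing its timestamp.

    Returns ``(by_period, dropped)`` where ``by_period`` maps every period
    label (including empty ones) to its records in input order and
    ``dropped`` holds the records outside all periods.  Assignment follows
    the half-open convention: a record exactly on a period's start boundary
    belongs to that period.
    """
    by_period: dict[str, list[CallRecord]] = {label: [] for label in partition.labels}
    dropped: list[CallRecord] = []
    for rec in records:
        label = partition.locate(rec.timestamp)
        if label is None:
            dropped.append(rec)
        else:
            by_period[label].append(rec)
    if dropped:
        log.info("assign_periods: %d record(s) outside the partition window", len(dropped))
    return by_period, dropped


def select_direction(records: Sequence[CallRecord], mode: Mode | str) -> list[CallRecord]:
    """Filter records by call direction; ``total`` keeps everything."""
    mode = Mode(mode)
    if mode is Mode.TOTAL:
        return list(records)
    wanted = Direction(mode.value)
    return [rec for rec in records if rec.direction is wanted]


def period_summary(
    by_period: Mapping[str, Sequence[CallRecord]], dropped: Sequence[CallRecord]
) -> str:
    """JSON summary of per-period record counts (for run logs)."""
    return json.dumps(
        {
            "periods": {label: len(recs) for label, recs in by_period.items()},
            "dropped": len(dropped),
        }
    )
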