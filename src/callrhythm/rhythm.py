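"""Hourly daily-rhythm profiles.

The daily rhythm of individual ``i`` in a period is the empirical
distribution of their calls over the 24 hour-of-day slots:

    f_i(t) = n_i(t) / sum_t n_i(t),   t in 0..23,

where ``n_i(t)`` is the number of calls whose timestamp falls in slot
``[t, t+1)``.  No smoothing or pseudo-counts are applied — the rhythm is
the raw empirical fraction, so it is undefined for an empty period.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cdr_io import CallRecord, Mode

__all__ = ["HourlyCounts", "DailyRhythm", "EmptyPeriodError", "count_by_hour", "compute_rhythm", "write_rhythms"]

N_HOURS = 24

_SUM_TOL = 1e-12


class EmptyPeriodError(ValueError):
    """Raised when a rhythm is requested for a period with zero calls."""

    def __init__(self, owner_id: str, period: str, mode: Mode):
        self.owner_id, self.period, self.mode = owner_id, period, mode
        super().__init__(
            f"no calls for owner {owner_id!r} in period {period!r} "
            f"(mode {mode.value}); rhythm undefined — exclude this individual"
        )


@dataclass(frozen=True)
class HourlyCounts:
    """24-bin call counts for one individual, period and direction mode."""

    owner_id: str
    period: str
    mode: Mode
    counts: np.ndarray  # shape (24,), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_HOURS,):
            raise ValueError(f"counts must have shape (24,), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DailyRhythm:
    """Normalised daily rhythm f_i(t): a 24-bin probability distribution."""

    owner_id: str
    period: str
    mode: Mode
    fractions: np.ndarray  # shape (24,), sums to 1
    total_calls: int

    def __post_init__(self) -> None:
        fractions = np.asarray(self.fractions, dtype=np.float64)
        if fractions.shape != (N_HOURS,):
            raise ValueError(f"fractions must have shape (24,), got {fractions.shape}")
        if (fractions < 0).any() or (fractions > 1).any():
            raise ValueError("fractions must lie in [0, 1]")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {fractions.sum()}")
        if self.total_calls < 1:
            raise ValueError("a rhythm requires at least one call")
        object.__setattr__(self, "fractions", fractions)


def count_by_hour(
    records: Sequence[CallRecord],
    *,
    owner_id: str | None = None,
    period: str = "",
    mode: Mode = Mode.TOTAL,
) -> HourlyCounts:
    """Bin records into the 24 hour-of-day slots.

    All records are assumed to belong to one owner, period and mode (the
    caller selects them beforehand).  The slot of a call is the hour field
    of its timestamp, i.e. slot ``[h, h+1)``.
    """
    if owner_id is None:
        owner_id = records[0].owner_id if records else ""
    counts = np.zeros(N_HOURS, dtype=np.int64)
    for rec in records:
        counts[rec.timestamp.hour] += 1
    return HourlyCounts(owner_id=owner_id, period=period, mode=mode, counts=counts)


def compute_rhythm(counts: HourlyCounts) -> DailyRhythm:
    """Normalise hourly counts into the daily rhythm f_i(t) = n_i(t)/Σn_i(t).

    Raises :class:`EmptyPeriodError` when the period holds no calls; the
    individual must then be excluded from that mode's analysis.
    """
    total = counts.total
    if total == 0:
        raise EmptyPeriodError(counts.owner_id, counts.period, counts.mode)
    return DailyRhythm(
        owner_id=counts.owner_id,
        period=counts.period,
        mode=counts.mode,
        fractions=counts.counts / total,
        total_calls=total,
    )


def write_rhythms(rhythms: Iterable[DailyRhythm], path: str | Path) -> None:
    """Export rhythms as tidy CSV: owner_id, period, mode, hour, fraction."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["owner_id", "period", "mode", "hour", "fraction"])
        for r in rhythms:
            for hour in range(N_HOURS):
                writer.writerow([r.owner_id, r.period, r.mode.value, hour, repr(float(r.fractions[hour]))])
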