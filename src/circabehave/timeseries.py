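"""Binned activity records, per-second mobility traces, and day folding.

An :class:`ActivityRecord` holds wheel-revolution counts in fixed-width
bins (3 min by default).  Missing bins are carried as ``NaN`` sentinels
and excluded from every downstream mean — they are never zero-filled,
because zero-filling biases nocturnality and rhythm power.

All day arithmetic uses half-open days ``[ZT0, ZT0 + 24 h)`` and
0-based bin indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParseError, ValidationError
from .schedule import LightSchedule

MINUTES_PER_DAY = 1440.0


@dataclass
class ActivityRecord:
    """Binned event-count time series with its lighting schedule.

    ``start_time`` is in hours relative to ZT0 of day 0.  Counts are
    non-negative; NaN marks a missing bin.  In-memory counts may be
    non-integer (deterministic simulations produce fractional expected
    counts in partial bins); file I/O coerces to integers.
    """

    counts: np.ndarray
    bin_minutes: float = 3.0
    start_time: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule.dd)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValidationError("counts must be one-dimensional")
        if self.bin_minutes <= 0:
            raise ValidationError("bin_minutes must be positive")
        if abs(60.0 / self.bin_minutes - round(60.0 / self.bin_minutes)) > 1e-9:
            raise ValidationError("bin_minutes must divide 60")
        finite = self.counts[np.isfinite(self.counts)]
        if (finite < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_gaps(self) -> int:
        return int(np.isnan(self.counts).sum())

    @property
    def bins_per_day(self) -> int:
        return int(round(MINUTES_PER_DAY / self.bin_minutes))

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_minutes / 60.0


@dataclass
class MobilityTrace:
    """Per-sample immobility fractions (fraction of animal area immobile)."""

    immobility: np.ndarray
    sample_seconds: float = 1.0
    start_time: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule.ld)

    def __post_init__(self) -> None:
        self.immobility = np.asarray(self.immobility, dtype=float)
        if self.sample_seconds <= 0:
            raise ValidationError("sample_seconds must be positive")
        v = self.immobility
        if ((v < 0) | (v > 1)).any():
            raise ValidationError("immobility values must lie in [0, 1]")

    @property
    def duration_hours(self) -> float:
        return self.immobility.size * self.sample_seconds / 3600.0


@dataclass
class DayMatrix:
    """Day x bin grid of counts (or sleep seconds); every row spans 24 h."""

    values: np.ndarray
    bin_minutes: float
    day0: int = 0  # day index (from record start_time's day frame) of row 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValidationError("DayMatrix needs at least one full day")
        expected = int(round(MINUTES_PER_DAY / self.bin_minutes))
        if self.values.shape[1] != expected:
            raise ValidationError("each row must span exactly 24 h")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def days(self) -> np.ndarray:
        return self.day0 + np.arange(self.n_days)


def fold_days(record: ActivityRecord) -> DayMatrix:
    """Fold a record into a day x bin matrix, trimming partial days.

    The record is aligned to the ZT0 grid implied by ``start_time``:
    leading bins up to the next ZT0 boundary and trailing bins of an
    incomplete final day are dropped.  The matrix sum equals the sum of
    the surviving counts.
    """
    bpd = record.bins_per_day
    offset = int(round(record.start_time * 60.0 / record.bin_minutes))
    lead = (-offset) % bpd
    usable = record.n_bins - lead
    n_days = usable // bpd
    if n_days < 1:
        raise InsufficientDataError("record spans less than one full day after trimming")
    data = record.counts[lead : lead + n_days * bpd].reshape(n_days, bpd)
    day0 = (offset + lead) // bpd
    return DayMatrix(data, record.bin_minutes, day0=day0)


def resample_bins(record: ActivityRecord, new_bin_minutes: float) -> ActivityRecord:
    """Sum counts into coarser bins; total count is conserved exactly.

    ``new_bin_minutes`` must be an integer multiple of the current bin
    width and the record length must be divisible by the factor (always
    true for day-aligned records).  Any group containing a gap becomes a
    gap.
    """
    ratio = new_bin_minutes / record.bin_minutes
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValidationError("new bin width must be an integer multiple of the old")
    if factor == 1:
        return ActivityRecord(record.counts.copy(), record.bin_minutes, record.start_time, record.schedule)
    if record.n_bins % factor:
        raise ValidationError("record length is not divisible by the resampling factor")
    grouped = record.counts.reshape(-1, factor)
    sums = grouped.sum(axis=1)  # NaN propagates: a gap poisons its group
    return ActivityRecord(sums, new_bin_minutes, record.start_time, record.schedule)


# ----------------------------------------------------------------------
# I/O: plain-text CSV, one bin per line (count only, or timestamp,count)
# ----------------------------------------------------------------------

def read_activity_csv(
    path,
    bin_minutes: float = 3.0,
    schedule: LightSchedule | None = None,
    start_time: float = 0.0,
) -> ActivityRecord:
    """Read a binned activity file.

    Accepts either a single column of counts per bin (empty field = gap)
    or two comma-separated columns ``elapsed_minutes,count`` on the bin
    grid, where absent grid rows become gaps.  Counts are coerced to
    non-negative integers; negative values raise :class:`ValidationError`
    and malformed rows raise :class:`ParseError` naming the line.
    """
    schedule = schedule or LightSchedule.dd()
    lines = Path(path).read_text().splitlines()
    rows: list[tuple[float | None, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if not line and lineno <= len(lines):
                rows.append((None, np.nan))  # blank line = explicit gap
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            if len(parts) == 1:
                val = np.nan if parts[0] == "" else float(parts[0])
                rows.append((None, val))
            elif len(parts) == 2:
                rows.append((float(parts[0]), float(parts[1])))
            else:
                raise ValueError
        except ValueError:
            raise ParseError(f"{path}: malformed row at line {lineno}: {raw!r}") from None
    if not rows:
        raise ParseError(f"{path}: empty file")

    stamped = [r for r in rows if r[0] is not None]
    if stamped and len(stamped) != len(rows):
        raise ParseError(f"{path}: mixed one-column and two-column rows")
    if stamped:
        t = np.array([r[0] for r in rows])
        v = np.array([r[1] for r in rows])
        idx = t / bin_minutes
        if np.max(np.abs(idx - np.round(idx))) > 1e-6:
            raise ParseError(f"{path}: timestamps are not on the {bin_minutes}-min bin grid")
        idx = np.round(idx).astype(int)
        idx -= idx[0]
        counts = np.full(idx[-1] + 1, np.nan)
        counts[idx] = v
    else:
        counts = np.array([r[1] for r in rows])

    finite = np.isfinite(counts)
    if (counts[finite] < 0).any():
        bad = np.flatnonzero(finite & (counts < 0))[0]
        raise ValidationError(f"{path}: negative count at bin {bad}")
    counts[finite] = np.round(counts[finite])
    return ActivityRecord(counts, bin_minutes, start_time, schedule)


def write_activity_csv(record: ActivityRecord, path) -> None:
    """Write one count per line; gaps become empty lines."""
    with open(path, "w") as fh:
        for c in record.counts:
            fh.write("" if np.isnan(c) else str(int(round(c))))
            fh.write("\n")


def read_mobility_csv(
    path,
    sample_seconds: float = 1.0,
    schedule: LightSchedule | None = None,
    start_time: float = 0.0,
) -> MobilityTrace:
    """Read a single-column per-sample immobility-fraction file."""
    schedule = schedule or LightSchedule.ld()
    try:
        vals = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    return MobilityTrace(vals, sample_seconds, start_time, schedule)


def write_mobility_csv(trace: MobilityTrace, path) -> None:
    np.savetxt(path, trace.immobility, fmt="%.6g")
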