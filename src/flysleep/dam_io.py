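"""Reading and writing Trikinetics DAM monitor files.

The DAMSystem ASCII layout is one tab-delimited row per minute with 42
fields: record index, date (``"D Mon YY"``), time (``"HH:MM:SS"``), a status
code (1 = valid reading), six metadata fields, then 32 per-channel beam-cross
counts.  Counts are non-negative integers — the number of times the fly broke
the infrared beam in that minute.

Zeitgeber time (ZT) convention: ZT0 is lights-on, ZT720 (minutes) is
lights-off in a 12:12 light–dark cycle, ZT1440 the end of the night.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

N_CHANNELS = 32
_N_FIELDS = 10 + N_CHANNELS
_DATE_FORMAT = "%d %b %y"

MINUTES_PER_DAY = 1440


class MonitorParseError(ValueError):
    """Raised when a DAM monitor file violates the expected dialect."""


class WindowGapError(ValueError):
    """Raised when an extraction window is not covered by contiguous valid minutes."""

    def __init__(self, message: str, missing: list[datetime]):
        super().__init__(message)
        self.missing = missing


@dataclass(frozen=True)
class MonitorRecord:
    """One minute of readings from a 32-channel DAM monitor."""

    record_index: int
    timestamp: datetime
    status: int
    counts: tuple[int, ...]  # 32 beam-cross counts, channels 1..32
    metadata: tuple[int, ...] = (0, 0, 0, 0, 0, 0)

    @property
    def is_valid(self) -> bool:
        return self.status == 1


@dataclass
class MonitorRecordSet:
    """All rows of one monitor file, in file order."""

    rows: list[MonitorRecord]
    path: str | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass
class BeamCountSeries:
    """Per-minute beam-cross counts for one fly, aligned to Zeitgeber time.

    Parameters
    ----------
    counts
        Non-negative integer counts, one per minute.
    start_zt
        Zeitgeber minute of the first sample (0 = lights-on).
    zt0_offset
        Minute-of-day at which lights turn on (clock time of ZT0).
    photoperiod_min
        Length of the light phase in minutes (720 for a 12:12 LD cycle).
    """

    counts: np.ndarray
    start_zt: int = 0
    zt0_offset: int = 0
    monitor_id: str = ""
    channel: int = 0
    photoperiod_min: int = 720
    genotype: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("beam-cross counts must be non-negative")
        if not 0 <= self.start_zt < MINUTES_PER_DAY:
            raise ValueError(f"start_zt must be in [0, 1440), got {self.start_zt}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def zt_minutes(self) -> np.ndarray:
        """ZT minute (mod 1440) of each sample."""
        return (self.start_zt + np.arange(len(self.counts))) % MINUTES_PER_DAY


def _parse_row(line: str, lineno: int) -> MonitorRecord:
    fields = line.rstrip("\n").rstrip("\r").split("\t")
    if len(fields) < _N_FIELDS:
        raise MonitorParseError(
            f"line {lineno}: expected {_N_FIELDS} tab-delimited fields, got {len(fields)}"
        )
    try:
        record_index = int(fields[0])
    except ValueError as exc:
        raise MonitorParseError(f"line {lineno}: bad record index {fields[0]!r}") from exc
    try:
        date = datetime.strptime(fields[1], _DATE_FORMAT)
    except ValueError as exc:
        raise MonitorParseError(f"line {lineno}: unparseable date {fields[1]!r}") from exc
    time_parts = fields[2].split(":")
    if len(time_parts) != 3:
        raise MonitorParseError(f"line {lineno}: unparseable time {fields[2]!r}")
    try:
        hh, mm, ss = (int(p) for p in time_parts)
    except ValueError as exc:
        raise MonitorParseError(f"line {lineno}: unparseable time {fields[2]!r}") from exc
    if not (0 <= hh < 24 and 0 <= mm < 60 and 0 <= ss < 60):
        raise MonitorParseError(f"line {lineno}: time out of range {fields[2]!r}")
    if ss != 0:
        logger.warning("line %d: seconds field %02d truncated to minute resolution", lineno, ss)
    timestamp = date.replace(hour=hh, minute=mm, second=0)
    try:
        status = int(fields[3])
        metadata = tuple(int(f) for f in fields[4:10])
        counts = tuple(int(f) for f in fields[10:_N_FIELDS])
    except ValueError as exc:
        raise MonitorParseError(f"line {lineno}: non-integer field") from exc
    if any(c < 0 for c in counts):
        raise MonitorParseError(f"line {lineno}: negative beam-cross count")
    return MonitorRecord(record_index, timestamp, status, counts, metadata)


def parse_monitor_file(path: str | Path) -> MonitorRecordSet:
    """Parse a DAM monitor file into a :class:`MonitorRecordSet`.

    Rows with a non-1 status code are retained (flagged via
    :attr:`MonitorRecord.is_valid`); malformed rows raise
    :class:`MonitorParseError` naming the offending line.
    """
    path = Path(path)
    rows: list[MonitorRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rows.append(_parse_row(line, lineno))
    if not rows:
        raise MonitorParseError(f"{path}: empty monitor file")
    return MonitorRecordSet(rows=rows, path=str(path))


def write_monitor_file(records: MonitorRecordSet, path: str | Path) -> None:
    """Write records in the canonical DAM dialect (inverse of :func:`parse_monitor_file`)."""
    with open(path, "w") as fh:
        for rec in records.rows:
            fields = [
                str(rec.record_index),
                rec.timestamp.strftime(_DATE_FORMAT).lstrip("0"),
                rec.timestamp.strftime("%H:%M:%S"),
                str(rec.status),
                *(str(m) for m in rec.metadata),
                *(str(c) for c in rec.counts),
            ]
            fh.write("\t".join(fields) + "\n")


def extract_channel_series(
    records: MonitorRecordSet,
    channel: int,
    window_start: datetime,
    window_minutes: int,
    lights_on_clock: int = 0,
    monitor_id: str | None = None,
) -> BeamCountSeries:
    """Extract one fly's count series over a time window.

    Parameters
    ----------
    channel
        DAM channel number, 1..32.
    window_start
        Timestamp (minute resolution) of the first minute wanted.
    window_minutes
        Window length; every minute must be present with status 1.
    lights_on_clock
        Minute-of-day at which lights turn on; used to align the series to
        Zeitgeber time (a window starting at lights-on has ``start_zt == 0``).

    Raises
    ------
    WindowGapError
        If any minute of the window is absent or recorded with an error
        status; the exception lists the missing timestamps.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be in 1..{N_CHANNELS}, got {channel}")
    if window_minutes < 1:
        raise ValueError("window_minutes must be >= 1")
    window_start = window_start.replace(second=0, microsecond=0)
    by_time = {rec.timestamp: rec for rec in records.rows}
    wanted = [window_start + timedelta(minutes=i) for i in range(window_minutes)]
    missing = [t for t in wanted if t not in by_time or not by_time[t].is_valid]
    if missing:
        shown = ", ".join(t.isoformat() for t in missing[:5])
        raise WindowGapError(
            f"window has {len(missing)} missing/invalid minutes (first: {shown})", missing
        )
    counts = np.array([by_time[t].counts[channel - 1] for t in wanted], dtype=np.int64)
    minute_of_day = window_start.hour * 60 + window_start.minute
    start_zt = (minute_of_day - lights_on_clock) % MINUTES_PER_DAY
    return BeamCountSeries(
        counts=counts,
        start_zt=start_zt,
        zt0_offset=lights_on_clock,
        monitor_id=monitor_id or (records.path or ""),
        channel=channel,
    )
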