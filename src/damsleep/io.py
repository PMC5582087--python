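"""Reading and writing Trikinetics-style DAM monitor files.

The DAM acquisition software writes one tab-separated line per reading:
a running index, date (``1 Jun 16``), time (``HH:MM:SS``), a status code
(1 = valid), a handful of device fields, the light-sensor flag, and then
one beam-crossing count per channel (32 channels per monitor).  The exact
field layout varies between deployments, so it is configurable through
:class:`Dialect`; the default matches common DAMSystem monitor exports
(42 fields, 5 padding fields between status and light flag).

Readings with a status code other than 1 are kept but recorded in the
table's validation report and masked when a channel is extracted — they are
never silently dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .series import ActivitySeries, LightSchedule

N_CHANNELS = 32


class DamFormatError(ValueError):
    """Unparseable content in a monitor file (bad date/time, bad count)."""


class DamDialectError(ValueError):
    """Line structure does not match the configured dialect."""


@dataclass(frozen=True)
class Dialect:
    """Field layout of a DAM monitor file.

    Column indices are 0-based positions among the tab-separated fields.
    """

    n_fields: int = 42
    index_col: int = 0
    date_col: int = 1
    time_col: int = 2
    status_col: int = 3
    light_col: int = 9
    first_count_col: int = 10
    date_format: str = "%d %b %y"
    n_channels: int = N_CHANNELS


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class ValidationIssue:
    line: int          # 1-based line number in the file
    kind: str          # e.g. "status"
    detail: str


@dataclass
class MonitorTable:
    """Parsed monitor file: timestamped readings x 32 channels of counts."""

    monitor_id: str
    index: np.ndarray          # running reading index, strictly increasing
    timestamps: list[dt.datetime]
    status: np.ndarray
    light: np.ndarray
    counts: np.ndarray         # shape (n_readings, 32)
    interval_minutes: int
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_readings(self) -> int:
        return int(self.counts.shape[0])

    def validate(self) -> None:
        if self.n_readings == 0:
            return
        if self.counts.shape[1] != N_CHANNELS:
            raise ValueError("a monitor table must have exactly 32 channels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (np.diff(self.index) > 0).all():
            raise ValueError("reading indices must be strictly increasing")
        deltas = {
            (b - a).total_seconds()
            for a, b in zip(self.timestamps[:-1], self.timestamps[1:])
        }
        if deltas:
            if min(deltas) <= 0:
                raise ValueError("timestamps must be strictly increasing")
            if len(deltas) > 1:
                raise ValueError("timestamps must have constant spacing")
            if deltas != {self.interval_minutes * 60.0}:
                raise ValueError("timestamp spacing must equal interval_minutes")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MonitorTable):
            return NotImplemented
        return (
            self.monitor_id == other.monitor_id
            and np.array_equal(self.index, other.index)
            and self.timestamps == other.timestamps
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.light, other.light)
            and np.array_equal(self.counts, other.counts)
            and self.interval_minutes == other.interval_minutes
        )


def read_monitor_file(
    path: str | Path,
    dialect: Dialect | None = None,
    resort: bool = False,
) -> MonitorTable:
    """Parse a DAM monitor text file into a :class:`MonitorTable`.

    Non-status-1 readings are kept and listed in ``table.issues``.  Files
    whose lines are out of timestamp order are rejected unless
    ``resort=True``, in which case they are re-sorted explicitly.
    """
    d = dialect or DEFAULT_DIALECT
    path = Path(path)
    lines = path.read_text().splitlines()

    indices: list[int] = []
    stamps: list[dt.datetime] = []
    status: list[int] = []
    light: list[int] = []
    counts: list[list[int]] = []
    issues: list[ValidationIssue] = []

    ts_format = d.date_format + " %H:%M:%S"
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != d.n_fields:
            raise DamDialectError(
                f"{path.name}:{lineno}: expected {d.n_fields} tab-separated "
                f"fields, found {len(fields)}; configure a Dialect with "
                f"n_fields={len(fields)} if this layout is intentional"
            )
        try:
            ts = dt.datetime.strptime(
                f"{fields[d.date_col]} {fields[d.time_col]}", ts_format
            )
        except ValueError as exc:
            raise DamFormatError(
                f"{path.name}:{lineno}: unparseable date/time "
                f"{fields[d.date_col]!r} {fields[d.time_col]!r}"
            ) from exc
        try:
            idx = int(fields[d.index_col])
            st = int(fields[d.status_col])
            lt = int(fields[d.light_col])
            row = [int(v) for v in fields[d.first_count_col : d.first_count_col + d.n_channels]]
        except ValueError as exc:
            raise DamFormatError(f"{path.name}:{lineno}: non-integer field") from exc
        if len(row) != d.n_channels or any(v < 0 for v in row):
            raise DamFormatError(
                f"{path.name}:{lineno}: expected {d.n_channels} non-negative counts"
            )
        if st != 1:
            issues.append(
                ValidationIssue(line=lineno, kind="status", detail=f"status code {st}")
            )
        indices.append(idx)
        stamps.append(ts)
        status.append(st)
        light.append(lt)
        counts.append(row)

    if not indices:
        return MonitorTable(
            monitor_id=path.stem,
            index=np.empty(0, dtype=np.int64),
            timestamps=[],
            status=np.empty(0, dtype=np.int64),
            light=np.empty(0, dtype=np.int64),
            counts=np.empty((0, d.n_channels), dtype=np.int64),
            interval_minutes=1,
            issues=issues,
        )

    order = np.arange(len(stamps))
    if any(b <= a for a, b in zip(stamps[:-1], stamps[1:])):
        if not resort:
            raise DamFormatError(
                f"{path.name}: timestamps are not strictly increasing "
                "(pass resort=True to re-sort explicitly)"
            )
        order = np.argsort(np.array(stamps, dtype="datetime64[s]"), kind="stable")

    index = np.asarray(indices, dtype=np.int64)[order]
    stamps = [stamps[i] for i in order]
    interval = (
        int(round((stamps[1] - stamps[0]).total_seconds() / 60.0))
        if len(stamps) > 1
        else 1
    )
    table = MonitorTable(
        monitor_id=path.stem,
        index=index,
        timestamps=stamps,
        status=np.asarray(status, dtype=np.int64)[order],
        light=np.asarray(light, dtype=np.int64)[order],
        counts=np.asarray(counts, dtype=np.int64)[order],
        interval_minutes=max(interval, 1),
        issues=issues,
    )
    table.validate()
    return table


def _format_date(ts: dt.datetime) -> str:
    # DAM files use a non-zero-padded day of month ("1 Jun 16").
    return f"{ts.day} {ts.strftime('%b %y')}"


def write_monitor_file(
    table: MonitorTable, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write a :class:`MonitorTable` back to DAM text format.

    ``read_monitor_file`` on the output reproduces the table exactly, and a
    second write of the re-read table is byte-identical.
    """
    d = dialect or DEFAULT_DIALECT
    table.validate()
    n_pad = d.light_col - d.status_col - 1
    lines = []
    for i in range(table.n_readings):
        ts = table.timestamps[i]
        fields = [
            str(int(table.index[i])),
            _format_date(ts),
            ts.strftime("%H:%M:%S"),
            str(int(table.status[i])),
            *(["0"] * n_pad),
            str(int(table.light[i])),
            *(str(int(v)) for v in table.counts[i]),
        ]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def to_activity_series(
    table: MonitorTable,
    channel: int,
    schedule: LightSchedule | None = None,
    fly_id: str | None = None,
) -> ActivitySeries:
    """Extract one channel (1..32) as an :class:`ActivitySeries`.

    Bins from non-status-1 readings are masked as missing; counts are
    otherwise carried unchanged, so the series total equals the channel's
    column sum over valid readings.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise IndexError(f"channel must be in 1..{N_CHANNELS}, got {channel}")
    if table.n_readings == 0:
        raise ValueError("cannot extract a series from an empty monitor table")
    return ActivitySeries(
        fly_id=fly_id or f"{table.monitor_id}:ch{channel:02d}",
        counts=table.counts[:, channel - 1],
        bin_minutes=table.interval_minutes,
        start=table.timestamps[0],
        schedule=schedule or LightSchedule(),
        mask=table.status == 1,
    )


def table_from_series(
    series_list: list[ActivitySeries],
    monitor_id: str = "M001",
    start_index: int = 1,
) -> MonitorTable:
    """Assemble up to 32 aligned series into a monitor table (channel order).

    Unused channels are filled with zero counts.  All series must share
    start, length and bin size.
    """
    if not series_list:
        raise ValueError("need at least one series")
    if len(series_list) > N_CHANNELS:
        raise ValueError("a monitor holds at most 32 channels")
    first = series_list[0]
    for s in series_list[1:]:
        if (s.start, s.n_bins, s.bin_minutes) != (first.start, first.n_bins, first.bin_minutes):
            raise ValueError("all series must be aligned to share a monitor")
    n = first.n_bins
    counts = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, s in enumerate(series_list):
        counts[:, ch] = s.counts
    zt = first.zt_minutes()
    light = (zt < first.schedule.light_hours * 60).astype(np.int64)
    stamps = [first.bin_start(i) for i in range(n)]
    table = MonitorTable(
        monitor_id=monitor_id,
        index=np.arange(start_index, start_index + n, dtype=np.int64),
        timestamps=stamps,
        status=np.ones(n, dtype=np.int64),
        light=light,
        counts=counts,
        interval_minutes=first.bin_minutes,
    )
    table.validate()
    return table
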