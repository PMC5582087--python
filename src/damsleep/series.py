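"""Core containers: light schedule and per-fly activity series.

A Drosophila Activity Monitor (DAM) counts infrared-beam crossings per
recording interval for each of 32 flies.  Downstream analysis works on one
fly at a time as an :class:`ActivitySeries` — a uniformly binned count
vector with its start timestamp, bin size, validity mask and the light/dark
entrainment schedule attached.  All Zeitgeber-time (ZT) arithmetic goes
through :class:`LightSchedule`; timestamps themselves are timezone-naive
local time.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class LightSchedule:
    """An LD entrainment cycle anchored at lights-on.

    ZT0 is defined as lights-on; ZT12 is lights-off under the default
    12:12 h light:dark cycle with lights on at 08:00 local time.
    """

    lights_on: dt.time = dt.time(8, 0)
    light_hours: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.light_hours < 24:
            raise ValueError("light_hours must be in (0, 24)")

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours

    def anchor(self, ts: dt.datetime) -> dt.datetime:
        """Most recent lights-on instant at or before ``ts`` (a ZT0 mark)."""
        candidate = dt.datetime.combine(ts.date(), self.lights_on)
        if candidate > ts:
            candidate -= dt.timedelta(days=1)
        return candidate

    def zt_hours(self, ts: dt.datetime) -> float:
        """Zeitgeber time of ``ts`` in hours, in [0, 24)."""
        delta = ts - self.anchor(ts)
        return (delta.total_seconds() / 3600.0) % 24.0

    def is_light(self, zt_hours: float) -> bool:
        return (zt_hours % 24.0) < self.light_hours


@dataclass
class ActivitySeries:
    """One fly's uniformly binned beam-crossing counts.

    ``mask`` flags valid bins (True = valid reading); bins from non-status-1
    monitor readings are carried but masked, and downstream scoring treats
    them as missing.
    """

    fly_id: str
    counts: np.ndarray
    bin_minutes: int
    start: dt.datetime
    schedule: LightSchedule = field(default_factory=LightSchedule)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts")

    # -- geometry -----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(minutes=self.n_bins * self.bin_minutes)

    def bin_start(self, i: int) -> dt.datetime:
        return self.start + dt.timedelta(minutes=i * self.bin_minutes)

    def total(self) -> int:
        return int(self.counts[self.mask].sum())

    # -- ZT coordinates -----------------------------------------------------
    def minutes_from_anchor(self) -> np.ndarray:
        """Minutes of each bin start since the anchoring ZT0 (lights-on)."""
        anchor = self.schedule.anchor(self.start)
        offset = (self.start - anchor).total_seconds() / 60.0
        return offset + np.arange(self.n_bins) * float(self.bin_minutes)

    def zt_minutes(self) -> np.ndarray:
        """ZT of each bin start, in minutes within [0, 1440)."""
        return self.minutes_from_anchor() % MINUTES_PER_DAY

    def zt_days(self) -> np.ndarray:
        """1-based ZT day index of each bin (day boundary at lights-on)."""
        return (self.minutes_from_anchor() // MINUTES_PER_DAY).astype(int) + 1

    def clock_minutes(self) -> np.ndarray:
        """Clock time of each bin start, minutes after local midnight."""
        base = self.start.hour * 60 + self.start.minute + self.start.second / 60.0
        return (base + np.arange(self.n_bins) * float(self.bin_minutes)) % MINUTES_PER_DAY

    def replace(self, **kwargs) -> "ActivitySeries":
        return dataclasses.replace(self, **kwargs)
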