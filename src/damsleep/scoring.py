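"""Sleep scoring, death calling and episode-partitioned daily summaries.

Fly sleep is scored by the standard inactivity rule: any run of at least
5 consecutive minutes with zero beam crossings counts as sleep.  Maximal
such runs are *sleep bouts*; bouts of at most 60 min are "short-term"
(fragmented) sleep, bouts longer than 1 h are "long-term" sleep.  A fly is
called dead when its terminal immobility exceeds 24 h, with the death time
placed at the end of the last bin containing activity.

Daily summaries partition each day into four clock-time episodes —
night 22:00–04:00, morning 04:00–12:00, siesta 12:00–16:00 and evening
16:00–22:00 (ZT14–20, ZT20–4, ZT4–8 and ZT8–14 for lights-on at 08:00).
Days run from lights-on (ZT0); the pre-ZT0 portion of the morning window
is attached to the following day so that each morning is contiguous.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import MINUTES_PER_DAY, ActivitySeries

SLEEP_THRESHOLD_MIN = 5
SHORT_BOUT_MAX_MIN = 60
IMMOBILITY_HOURS = 24.0

EPISODE_NAMES = ("night", "morning", "siesta", "evening")


@dataclass(frozen=True)
class SleepBout:
    """A maximal inactivity run of at least the sleep threshold."""

    start: dt.datetime
    duration_minutes: float

    @property
    def bout_class(self) -> str:
        return "short" if self.duration_minutes <= SHORT_BOUT_MAX_MIN else "long"

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(minutes=self.duration_minutes)


@dataclass(frozen=True)
class DeathCall:
    """Outcome of the terminal-immobility rule for one fly."""

    event: bool                 # True = death called, False = censored alive
    time: dt.datetime           # death time, or censoring time (series end)
    flag: str | None = None     # e.g. "never_active"

    def days_since(self, start: dt.datetime) -> float:
        return (self.time - start).total_seconds() / 86400.0


@dataclass(frozen=True)
class EpisodeWindows:
    """Four labeled clock-time windows tiling the 24-h day.

    Windows are given as (name, start, end) in minutes after local
    midnight; the night window wraps across midnight.
    """

    windows: tuple[tuple[str, int, int], ...] = (
        ("night", 22 * 60, 4 * 60),
        ("morning", 4 * 60, 12 * 60),
        ("siesta", 12 * 60, 16 * 60),
        ("evening", 16 * 60, 22 * 60),
    )

    def __post_init__(self) -> None:
        total = sum(self.length_minutes(name) for name, _, _ in self.windows)
        if total != MINUTES_PER_DAY:
            raise ValueError("episode windows must tile 24 h exactly")

    def length_minutes(self, name: str) -> int:
        for n, a, b in self.windows:
            if n == name:
                return (b - a) % MINUTES_PER_DAY
        raise KeyError(name)

    def episode_of(self, clock_minutes: np.ndarray) -> np.ndarray:
        """Label array for clock times (minutes after midnight)."""
        out = np.empty(clock_minutes.shape, dtype=object)
        cm = np.asarray(clock_minutes) % MINUTES_PER_DAY
        for name, a, b in self.windows:
            if a < b:
                sel = (cm >= a) & (cm < b)
            else:  # wraps midnight
                sel = (cm >= a) | (cm < b)
            out[sel] = name
        return out


DEFAULT_WINDOWS = EpisodeWindows()


# ---------------------------------------------------------------------------
# rebinning
# ---------------------------------------------------------------------------

def rebin(series: ActivitySeries, target_bin: int) -> ActivitySeries:
    """Sum counts into coarser aligned bins; totals are conserved.

    A 24-h day at 5-min bins has exactly 288 bins.  The target bin must be
    a multiple of the current bin and the series length must divide evenly.
    """
    if target_bin == series.bin_minutes:
        return series.replace()
    if target_bin % series.bin_minutes != 0:
        raise ValueError(
            f"target bin {target_bin} is not a multiple of {series.bin_minutes}"
        )
    factor = target_bin // series.bin_minutes
    if series.n_bins % factor != 0:
        raise ValueError("series length does not divide into the target bin")
    counts = series.counts.reshape(-1, factor).sum(axis=1)
    mask = series.mask.reshape(-1, factor).all(axis=1)
    return series.replace(counts=counts, bin_minutes=target_bin, mask=mask)


# ---------------------------------------------------------------------------
# sleep bouts
# ---------------------------------------------------------------------------

def detect_sleep_bouts(
    series: ActivitySeries, threshold_minutes: float = SLEEP_THRESHOLD_MIN
) -> list[SleepBout]:
    """Maximal zero-count runs of at least ``threshold_minutes``.

    Canonical scoring runs on 1-min bins.  On coarser bins every zero bin
    contributes its full width in sleep minutes, which approximates 1-min
    scoring at the display resolution (a single zero 5-min bin already
    satisfies the 5-min rule).  Masked bins are treated as missing and
    terminate runs.
    """
    if not series.mask.any():
        warnings.warn(f"{series.fly_id}: all bins masked; no bouts scored")
        return []
    zero = (series.counts == 0) & series.mask
    if not zero.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]
    bouts = []
    for i0, i1 in zip(starts, stops):
        duration = (i1 - i0) * series.bin_minutes
        if duration >= threshold_minutes:
            bouts.append(SleepBout(start=series.bin_start(int(i0)), duration_minutes=float(duration)))
    return bouts


def bouts_to_frame(fly_id: str, bouts: list[SleepBout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fly_id": fly_id,
            "start": [b.start for b in bouts],
            "duration_minutes": [b.duration_minutes for b in bouts],
            "bout_class": [b.bout_class for b in bouts],
        }
    )


# ---------------------------------------------------------------------------
# death calling
# ---------------------------------------------------------------------------

def call_death(
    series: ActivitySeries, immobility_hours: float = IMMOBILITY_HOURS
) -> DeathCall:
    """Terminal-immobility death call (immobility > ``immobility_hours``).

    If the zero-count run at the end of the recording strictly exceeds the
    immobility threshold, the fly is dead and the death time is the end of
    the last bin with a nonzero count; otherwise the fly is censored alive
    at the end of the recording.  A mid-series immobility run followed by
    resumed activity is never a death.  A fly with no activity at all is
    called dead at the series start and flagged ``"never_active"``.
    """
    active = (series.counts > 0) & series.mask
    if not active.any():
        return DeathCall(event=True, time=series.start, flag="never_active")
    last_active = int(np.flatnonzero(active)[-1])
    terminal_minutes = (series.n_bins - last_active - 1) * series.bin_minutes
    if terminal_minutes > immobility_hours * 60.0:
        return DeathCall(event=True, time=series.bin_start(last_active + 1))
    return DeathCall(event=False, time=series.end)


# ---------------------------------------------------------------------------
# episode partition and daily summaries
# ---------------------------------------------------------------------------

def _sleep_minutes_per_bin(
    series: ActivitySeries, bouts: list[SleepBout]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin sleep minutes split by bout class (short, long).

    A bout spanning a bin (hence episode) boundary is split pro-rata by
    overlap, so per-episode sleep tiles total sleep exactly.
    """
    short = np.zeros(series.n_bins)
    long_ = np.zeros(series.n_bins)
    b = series.bin_minutes
    for bout in bouts:
        t0 = (bout.start - series.start).total_seconds() / 60.0
        t1 = t0 + bout.duration_minutes
        target = short if bout.bout_class == "short" else long_
        i0 = max(int(t0 // b), 0)
        i1 = min(int(np.ceil(t1 / b)), series.n_bins)
        for i in range(i0, i1):
            lo, hi = i * b, (i + 1) * b
            target[i] += max(0.0, min(t1, hi) - max(t0, lo))
    return short, long_


def _day_assignment(
    series: ActivitySeries, windows: EpisodeWindows
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(calendar ZT day, episode-assigned day, episode label) per bin.

    The calendar day boundary is lights-on (ZT0).  Bins in the pre-ZT0
    portion of the morning window are re-assigned to the following day so
    each day's morning episode is one contiguous block.
    """
    cal_day = series.zt_days()
    clock = series.clock_minutes()
    episode = windows.episode_of(clock)
    lights_on = series.schedule.lights_on
    lights_on_min = lights_on.hour * 60 + lights_on.minute
    assigned = cal_day.copy()
    for name, a, b in windows.windows:
        if name != "morning":
            continue
        # portion of the morning window strictly before lights-on
        if a < b and a <= lights_on_min < b:
            pre = (clock >= a) & (clock < lights_on_min)
            assigned[pre] += 1
    return cal_day, assigned, episode


def partition_episodes(
    series: ActivitySeries,
    bouts: list[SleepBout],
    windows: EpisodeWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Per-day, per-episode activity counts and sleep minutes.

    Returns a tidy frame with one row per (day, episode); sleep from bouts
    spanning window boundaries is split pro-rata by overlap, so episode
    sleep totals tile the daily totals.
    """
    short, long_ = _sleep_minutes_per_bin(series, bouts)
    _, day, episode = _day_assignment(series, windows)
    df = pd.DataFrame(
        {
            "day": day,
            "episode": episode,
            "activity": np.where(series.mask, series.counts, 0),
            "sleep": short + long_,
            "sleep_short": short,
            "sleep_long": long_,
            "minutes": float(series.bin_minutes),
            "minutes_masked": np.where(series.mask, 0.0, float(series.bin_minutes)),
        }
    )
    out = df.groupby(["day", "episode"], as_index=False, sort=True).sum()
    return out


def summarize_daily(
    series: ActivitySeries,
    bouts: list[SleepBout] | None = None,
    death: DeathCall | None = None,
    windows: EpisodeWindows = DEFAULT_WINDOWS,
    min_coverage: float = 1.0,
    max_missing_frac: float = 0.05,
) -> pd.DataFrame:
    """One row per experiment day with totals and per-episode values.

    Day indexing is 1-based from the first lights-on at or before the
    recording start.  Edge days whose coverage (fraction of the 1440-min
    ZT day inside the recording) is below ``min_coverage`` are dropped
    (default: full days only).  Fly-days with more than
    ``max_missing_frac`` masked minutes are kept but excluded (NaN values).
    Days at or after the called death day carry ``alive=False`` and no
    behavioral values.
    """
    if bouts is None:
        bouts = detect_sleep_bouts(series)
    if death is None:
        death = call_death(series)

    cal_day, day, episode = _day_assignment(series, windows)
    short, long_ = _sleep_minutes_per_bin(series, bouts)

    # coverage judged on calendar ZT days (the recording span)
    days_idx, counts_per_day = np.unique(cal_day, return_counts=True)
    bins_per_day = MINUTES_PER_DAY / series.bin_minutes
    complete = days_idx[(counts_per_day / bins_per_day) >= min_coverage]
    if complete.size == 0:
        return pd.DataFrame(
            columns=["fly_id", "day", "alive", "excluded", *_summary_columns()]
        )

    death_day = None
    if death.event:
        anchor = series.schedule.anchor(series.start)
        death_day = int((death.time - anchor).total_seconds() // 86400) + 1

    per_bin = pd.DataFrame(
        {
            "day": day,
            "episode": episode,
            "activity": np.where(series.mask, series.counts, 0),
            "sleep": short + long_,
            "sleep_short": short,
            "sleep_long": long_,
            "masked_min": np.where(series.mask, 0.0, float(series.bin_minutes)),
        }
    )
    by_day = per_bin.groupby("day").sum(numeric_only=True)
    by_episode = per_bin.pivot_table(
        index="day", columns="episode", values=["activity", "sleep"], aggfunc="sum"
    )

    rows = []
    for d in complete:
        d = int(d)
        alive = death_day is None or d < death_day
        total_min = float((day == d).sum()) * series.bin_minutes
        masked = float(by_day.loc[d, "masked_min"]) if d in by_day.index else 0.0
        excluded = total_min > 0 and (masked / total_min) > max_missing_frac
        row: dict = {"fly_id": series.fly_id, "day": d, "alive": alive, "excluded": excluded}
        if alive and not excluded and d in by_day.index:
            row["activity"] = float(by_day.loc[d, "activity"])
            row["sleep"] = float(by_day.loc[d, "sleep"])
            row["sleep_short"] = float(by_day.loc[d, "sleep_short"])
            row["sleep_long"] = float(by_day.loc[d, "sleep_long"])
            for ep in EPISODE_NAMES:
                for metric in ("activity", "sleep"):
                    try:
                        row[f"{metric}_{ep}"] = float(by_episode.loc[d, (metric, ep)])
                    except KeyError:
                        row[f"{metric}_{ep}"] = 0.0
        else:
            for col in _summary_columns():
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_columns() -> list[str]:
    cols = ["activity", "sleep", "sleep_short", "sleep_long"]
    for ep in EPISODE_NAMES:
        cols += [f"activity_{ep}", f"sleep_{ep}"]
    return cols
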