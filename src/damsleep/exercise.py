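"""Swing-boat stimulation protocol and exercise-response statistics.

The rotating-tube ("swing boat") device tilts the monitor holding the fly
tubes, exploiting negative geotaxis to make flies walk.  The protocol used
here: rocking starts at ZT7 and lasts 30 min, at 3 tube turns per minute
(displacement 30 deg at 30 deg/s, ~17 s pause between motions), giving 90
stimuli per daily exercise unit over exercise days 1-12.

*Exercise success* for one fly-day is the percentage of the day's stimuli
that evoked at least one beam crossing; 100% means the fly moved after
every single tube rotation.  At recording resolutions coarser than the
inter-stimulus interval individual responses cannot be resolved, so a
capped estimator is used: per bin, min(counts, stimuli in bin) responses
are credited.  The estimator's mode is chosen from the bin size and can be
forced explicitly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import DEFAULT_WINDOWS, DeathCall, EpisodeWindows
from .series import MINUTES_PER_DAY, ActivitySeries


@dataclass(frozen=True)
class StimulusSchedule:
    """Per-day rocking stimulus timing of the swing-boat protocol."""

    start_zt: float = 7.0            # hours after lights-on
    duration_minutes: float = 30.0
    stimuli_per_minute: float = 3.0
    displacement_deg: float = 30.0
    angular_velocity_deg_s: float = 30.0
    pause_s: float = 17.0
    active_days: tuple[int, int] = (1, 12)   # inclusive day range

    def __post_init__(self) -> None:
        n = self.duration_minutes * self.stimuli_per_minute
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "duration x rate must give an integral stimulus count, got "
                f"{n}"
            )

    @property
    def stimuli_per_day(self) -> int:
        return int(round(self.duration_minutes * self.stimuli_per_minute))

    @property
    def interstimulus_seconds(self) -> float:
        return 60.0 / self.stimuli_per_minute if self.stimuli_per_minute else np.inf

    def stimulus_offsets_minutes(self) -> np.ndarray:
        """Stimulus times as minutes after window start (evenly spaced)."""
        n = self.stimuli_per_day
        if n == 0:
            return np.empty(0)
        return np.arange(n) / self.stimuli_per_minute

    def stimulus_zt_hours(self) -> np.ndarray:
        """Stimulus times for one active day, as ZT hours."""
        return self.start_zt + self.stimulus_offsets_minutes() / 60.0

    def is_active_day(self, day: int) -> bool:
        lo, hi = self.active_days
        return lo <= day <= hi

    def days(self) -> range:
        lo, hi = self.active_days
        return range(lo, hi + 1)


def build_stimulus_schedule(**params) -> StimulusSchedule:
    """Construct a schedule; defaults give 90 stimuli/day within ZT7-7.5."""
    return StimulusSchedule(**params)


def _window_bins(series: ActivitySeries, schedule: StimulusSchedule, day: int) -> np.ndarray:
    """Indices of bins overlapping the exercise window of a given ZT day."""
    m = series.minutes_from_anchor()
    w0 = (day - 1) * MINUTES_PER_DAY + schedule.start_zt * 60.0
    w1 = w0 + schedule.duration_minutes
    b = series.bin_minutes
    return np.flatnonzero((m + b > w0) & (m < w1))


def exercise_success(
    series: ActivitySeries,
    schedule: StimulusSchedule,
    day: int,
    mode: str = "auto",
) -> float:
    """Exercise-success percentage for one fly-day, in [0, 100].

    ``mode='fine'`` (bins no coarser than the inter-stimulus interval):
    each stimulus owns the response window up to the next stimulus (the
    last window closes at the end of the 30-min period) and scores a hit
    if any count falls inside.  ``mode='coarse'``: per bin,
    ``min(counts, stimuli in bin)`` responses are credited and divided by
    the total stimulus count.  Stimuli falling in masked bins are dropped
    from both numerator and denominator; a fully masked window gives NaN.
    """
    idx = _window_bins(series, schedule, day)
    if idx.size == 0:
        raise ValueError(f"series does not cover the exercise window of day {day}")
    n_stim = schedule.stimuli_per_day
    if n_stim == 0:
        return np.nan
    if mode == "auto":
        fine = series.bin_minutes * 60.0 <= schedule.interstimulus_seconds
        mode = "fine" if fine else "coarse"
    if mode not in ("fine", "coarse"):
        raise ValueError(f"unknown mode {mode!r}")

    m = series.minutes_from_anchor()
    b = float(series.bin_minutes)
    w0 = (day - 1) * MINUTES_PER_DAY + schedule.start_zt * 60.0
    stim_t = w0 + schedule.stimulus_offsets_minutes()
    w_end = w0 + schedule.duration_minutes

    if mode == "fine":
        next_t = np.append(stim_t[1:], w_end)
        hits = 0
        valid = 0
        for t0, t1 in zip(stim_t, next_t):
            sel = idx[(m[idx] + b > t0) & (m[idx] < t1)]
            if sel.size == 0 or not series.mask[sel].all():
                continue
            valid += 1
            if (series.counts[sel] > 0).any():
                hits += 1
        return np.nan if valid == 0 else 100.0 * hits / valid

    # coarse: capped estimator
    credited = 0.0
    valid_stim = 0
    for i in idx:
        in_bin = int(((stim_t >= m[i]) & (stim_t < m[i] + b)).sum())
        if in_bin == 0:
            continue
        if not series.mask[i]:
            continue
        valid_stim += in_bin
        credited += min(int(series.counts[i]), in_bin)
    return np.nan if valid_stim == 0 else 100.0 * credited / valid_stim


def fly_mean_success(
    series: ActivitySeries,
    schedule: StimulusSchedule,
    death: DeathCall | None = None,
    mode: str = "auto",
) -> tuple[float, pd.DataFrame]:
    """Mean success over the fly's valid exercise days, with per-day detail.

    Days at or after the called death day are excluded, matching the
    living-animals-only averaging used for all daily metrics.
    """
    anchor = series.schedule.anchor(series.start)
    death_day = None
    if death is not None and death.event:
        death_day = int((death.time - anchor).total_seconds() // 86400) + 1
    rows = []
    for day in schedule.days():
        covered = _window_bins(series, schedule, day).size > 0
        if not covered:
            continue
        alive = death_day is None or day < death_day
        value = exercise_success(series, schedule, day, mode=mode) if alive else np.nan
        rows.append({"day": day, "alive": alive, "success": value})
    detail = pd.DataFrame(rows)
    if detail.empty:
        return np.nan, detail
    valid = detail.loc[detail["alive"], "success"].dropna()
    return (float(valid.mean()) if len(valid) else np.nan), detail


def exercise_share(
    series: ActivitySeries,
    schedule: StimulusSchedule,
    windows: EpisodeWindows = DEFAULT_WINDOWS,
    death: DeathCall | None = None,
) -> tuple[float, pd.DataFrame]:
    """Induced activity as percent of voluntary peak activity.

    Per active day: 100 x (exercise-window counts) / (morning + evening
    counts).  Days with zero morning+evening activity are excluded and
    flagged; the returned scalar is the mean over included living days.
    """
    m = series.minutes_from_anchor()
    clock = series.clock_minutes()
    episode = windows.episode_of(clock)
    day_of_bin = series.zt_days()
    anchor = series.schedule.anchor(series.start)
    death_day = None
    if death is not None and death.event:
        death_day = int((death.time - anchor).total_seconds() // 86400) + 1

    rows = []
    for day in schedule.days():
        idx = _window_bins(series, schedule, day)
        if idx.size == 0:
            continue
        if death_day is not None and day >= death_day:
            continue
        window_counts = int(series.counts[idx][series.mask[idx]].sum())
        in_day = day_of_bin == day
        peaks = (episode == "morning") | (episode == "evening")
        sel = in_day & peaks & series.mask
        peak_counts = int(series.counts[sel].sum())
        rows.append(
            {
                "day": day,
                "window_counts": window_counts,
                "peak_counts": peak_counts,
                "share_pct": 100.0 * window_counts / peak_counts if peak_counts else np.nan,
                "flagged_zero_peaks": peak_counts == 0,
            }
        )
    detail = pd.DataFrame(rows)
    if detail.empty or detail["share_pct"].dropna().empty:
        return np.nan, detail
    return float(detail["share_pct"].dropna().mean()), detail


def group_success_summary(fly_means) -> dict:
    """Median and quartiles of per-fly mean successes (boxplot statistics)."""
    values = np.asarray(pd.Series(fly_means).dropna(), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one fly with a valid exercise day")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": int(values.size), "median": float(med), "q1": float(q1), "q3": float(q3)}
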