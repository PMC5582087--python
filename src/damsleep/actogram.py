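"""Actogram matrices and average daily activity profiles.

An actogram shows one row per experiment day and one column per 5-min
interval of the day, ZT-aligned so column 0 starts at lights-on; a full
LD day therefore has 288 columns.  Rendering follows the field's
conventions: per-row activity bars, a yellow/gray light-dark environment
bar, and a red marker over the exercise window on training days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exercise import StimulusSchedule
from .scoring import rebin
from .series import MINUTES_PER_DAY, ActivitySeries, LightSchedule

ACTOGRAM_BIN_MINUTES = 5
N_COLUMNS = MINUTES_PER_DAY // ACTOGRAM_BIN_MINUTES  # 288


@dataclass
class ActogramMatrix:
    """Day x 5-min-bin count matrix with NaN for missing/absent bins."""

    values: np.ndarray           # shape (n_days, 288)
    days: np.ndarray             # 1-based ZT day index per row
    exercise_days: np.ndarray    # bool per row
    fly_id: str

    @property
    def n_days(self) -> int:
        return int(self.values.shape[0])

    def total(self) -> float:
        return float(np.nansum(self.values))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"zt_{5 * k:04d}" for k in range(N_COLUMNS)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "day", self.days)
        df.insert(1, "exercise", self.exercise_days)
        return df


def actogram_matrix(
    series: ActivitySeries, exercise: StimulusSchedule | None = None
) -> ActogramMatrix:
    """ZT-aligned day x 288 matrix; column k covers ZT minutes [5k, 5k+5).

    The series is rebinned to 5 min if its bin divides 5; partial edge
    days are padded with NaN.  Masked bins render as missing, not zeros.
    """
    if series.bin_minutes != ACTOGRAM_BIN_MINUTES:
        if ACTOGRAM_BIN_MINUTES % series.bin_minutes != 0:
            raise ValueError("series bin size must divide 5 minutes")
        series = rebin(series, ACTOGRAM_BIN_MINUTES)
    day = series.zt_days()
    col = (series.zt_minutes() // ACTOGRAM_BIN_MINUTES).astype(int)
    days = np.unique(day)
    values = np.full((days.size, N_COLUMNS), np.nan)
    row_of = {int(d): i for i, d in enumerate(days)}
    rows = np.array([row_of[int(d)] for d in day])
    valid = series.mask
    values[rows[valid], col[valid]] = series.counts[valid]
    ex_flag = np.array(
        [exercise.is_active_day(int(d)) if exercise else False for d in days]
    )
    return ActogramMatrix(values=values, days=days, exercise_days=ex_flag, fly_id=series.fly_id)


def render_actogram(
    matrix: ActogramMatrix,
    schedule: LightSchedule,
    exercise: StimulusSchedule | None,
    path,
    double_plot: bool = False,
) -> None:
    """Render per-day activity bars with LD and exercise markers.

    Output is deterministic for a fixed input (fixed figure geometry,
    dpi and no timestamps), so repeated renders are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    values = matrix.values
    if double_plot:
        shifted = np.vstack([values[1:], np.full((1, N_COLUMNS), np.nan)])
        values = np.hstack([values, shifted])
    n_days, n_cols = values.shape
    vmax = np.nanmax(values) if np.isfinite(values).any() else 1.0
    vmax = max(vmax, 1.0)

    fig, ax = plt.subplots(figsize=(8, 0.28 * n_days + 1.2))
    x = np.arange(n_cols)
    for i in range(n_days):
        base = n_days - 1 - i
        row = values[i]
        ok = np.isfinite(row)
        h = np.zeros(n_cols)
        h[ok] = 0.9 * row[ok] / vmax
        ax.vlines(x[ok], base, base + h[ok], color="black", lw=0.6)
        if matrix.exercise_days[i] and exercise is not None:
            c0 = exercise.start_zt * 60.0 / ACTOGRAM_BIN_MINUTES
            c1 = (exercise.start_zt * 60.0 + exercise.duration_minutes) / ACTOGRAM_BIN_MINUTES
            ax.add_patch(
                Rectangle(
                    (c0, base), c1 - c0, 0.95, fill=False, edgecolor="red", lw=0.8
                )
            )
    # light-dark environmental bar above the raster
    reps = 2 if double_plot else 1
    light_cols = int(schedule.light_hours * 60 / ACTOGRAM_BIN_MINUTES)
    for r in range(reps):
        off = r * N_COLUMNS
        ax.add_patch(
            Rectangle((off, n_days + 0.2), light_cols, 0.6, color="gold", lw=0)
        )
        ax.add_patch(
            Rectangle(
                (off + light_cols, n_days + 0.2),
                N_COLUMNS - light_cols,
                0.6,
                color="0.6",
                lw=0,
            )
        )
    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_days + 1)
    ax.set_yticks([n_days - 1 - i + 0.5 for i in range(n_days)][:: max(n_days // 10, 1)])
    ax.set_yticklabels([str(int(d)) for d in matrix.days][:: max(n_days // 10, 1)])
    hours = np.arange(0, n_cols + 1, 6 * 60 // ACTOGRAM_BIN_MINUTES)
    ax.set_xticks(hours)
    ax.set_xticklabels([f"ZT{(h * ACTOGRAM_BIN_MINUTES // 60) % 24}" for h in hours])
    ax.set_xlabel("Zeitgeber time")
    ax.set_ylabel("day")
    ax.set_title(matrix.fly_id, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "damsleep"})
    plt.close(fig)


def daily_profile(
    series_list: list[ActivitySeries],
    day_range: tuple[int, int] = (1, 12),
    death_days: list[int | None] | None = None,
) -> np.ndarray:
    """Mean counts per 5-min ZT bin across flies and days (living only).

    ``death_days`` gives each fly's 1-based death day (None = censored);
    fly-days at or after death are excluded, matching the group-statistics
    convention.  Returns a 288-vector.
    """
    if not series_list:
        raise ValueError("need at least one series")
    if death_days is None:
        death_days = [None] * len(series_list)
    total = np.zeros(N_COLUMNS)
    n = np.zeros(N_COLUMNS)
    lo, hi = day_range
    for series, dday in zip(series_list, death_days):
        mat = actogram_matrix(series)
        for i, d in enumerate(mat.days):
            if not lo <= int(d) <= hi:
                continue
            if dday is not None and int(d) >= dday:
                continue
            row = mat.values[i]
            ok = np.isfinite(row)
            total[ok] += row[ok]
            n[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)
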