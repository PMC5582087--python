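"""Kaplan-Meier survival estimation and the two-group log-rank test.

Per-fly survival records come from the terminal-immobility death call:
time is days since the start of recording (fractional, at the resolution
of the recording bin), and flies still active at the end of the recording
are censored there.  The product-limit estimator and the Mantel-Cox
log-rank test are implemented directly; with no censoring the KM curve
reproduces the empirical survivor function and the median is the smallest
observed time t with S(t) <= 0.5.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DeathCall
from .series import ActivitySeries


@dataclass(frozen=True)
class SurvivalRecord:
    fly_id: str
    group: str
    time_days: float
    event: bool          # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("survival time must be positive")


def record_from_death(
    series: ActivitySeries, death: DeathCall, group: str
) -> SurvivalRecord:
    """Convert a death call into a survival record (time origin = recording start)."""
    t = death.days_since(series.start)
    # a never-active fly has death time == start; report the smallest
    # resolvable positive time (one bin) and keep the flag upstream
    t = max(t, series.bin_minutes / 1440.0)
    return SurvivalRecord(
        fly_id=series.fly_id, group=group, time_days=t, event=death.event
    )


@dataclass
class KMCurve:
    """Product-limit estimate: step function S(t) over event times."""

    times: np.ndarray            # distinct event times, ascending
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray         # S(t) just after each event time
    n_subjects: int
    median: float = field(default=np.nan)   # NaN = not reached

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function starting at 1."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate honoring right censoring."""
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.time_days for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    n = len(records)

    event_times = np.unique(times[events])
    at_risk = np.empty(event_times.size, dtype=np.int64)
    n_events = np.empty(event_times.size, dtype=np.int64)
    surv = np.empty(event_times.size)
    s = 1.0
    for k, t in enumerate(event_times):
        at_risk[k] = int((times >= t).sum())
        n_events[k] = int(((times == t) & events).sum())
        s *= 1.0 - n_events[k] / at_risk[k]
        surv[k] = s

    median = np.nan
    below = np.flatnonzero(surv <= 0.5)
    if below.size:
        median = float(event_times[below[0]])
    return KMCurve(
        times=event_times,
        at_risk=at_risk,
        n_events=n_events,
        survival=surv,
        n_subjects=n,
        median=median,
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float      # chi-square, 1 df
    p_value: float


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> LogrankResult:
    """Two-group Mantel-Cox log-rank test with hypergeometric tie variance."""
    if not group_a or not group_b:
        raise ValueError("both groups need at least one subject")
    ta = np.array([r.time_days for r in group_a])
    ea = np.array([r.event for r in group_a], dtype=bool)
    tb = np.array([r.time_days for r in group_b])
    eb = np.array([r.event for r in group_b], dtype=bool)
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    if all_event_times.size == 0:
        raise ValueError("need at least one observed event")

    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & ea).sum())
        d2 = int(((tb == t) & eb).sum())
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(statistic=0.0, p_value=1.0)
    chi2 = o_minus_e**2 / var
    return LogrankResult(statistic=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)))


def median_prolongation(
    treated_median: float, control_median: float
) -> tuple[float, float]:
    """Difference in median survival and percent change relative to control.

    E.g. medians 28.5 vs 21.5 days give (7.0 days, +32.6%).  Not-reached
    (NaN) medians propagate to NaN.
    """
    if not (np.isfinite(treated_median) and np.isfinite(control_median)):
        return (np.nan, np.nan)
    if control_median <= 0:
        raise ValueError("control median must be positive")
    diff = treated_median - control_median
    return (float(diff), float(100.0 * diff / control_median))


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fly_id": [r.fly_id for r in records],
            "group": [r.group for r in records],
            "time_days": [r.time_days for r in records],
            "event": [r.event for r in records],
        }
    )


def curve_to_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": curve.times,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
        }
    )


def plot_km(
    curves: dict[str, KMCurve],
    path,
    exercise_end_day: float | None = 12.0,
    colors: dict[str, str] | None = None,
) -> None:
    """Kaplan-Meier step plot with the end-of-exercise marker line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        x = np.concatenate([[0.0], np.repeat(curve.times, 2)])
        prev = np.concatenate([[1.0], curve.survival[:-1]]) if curve.times.size else np.empty(0)
        y = np.concatenate([[1.0], np.column_stack([prev, curve.survival]).ravel()]) \
            if curve.times.size else np.array([1.0])
        color = (colors or {}).get(label)
        ax.plot(x, y * 100.0, label=label, color=color, lw=1.5, drawstyle="default")
    if exercise_end_day is not None:
        ax.axvline(exercise_end_day, color="0.4", ls="--", lw=1.0)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival (%)")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
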