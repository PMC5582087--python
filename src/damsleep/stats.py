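"""Group-level daily averaging, control normalization and comparisons.

Daily group values average over all animals alive on that day
(living-animals-only convention), so the per-day n shrinks as flies die.
Relative metrics express a group as percent of a control group whose
value is taken as 100%.  Two range-summary conventions exist for day
windows (e.g. days 1-12 and 13-20): the mean of per-day ratios and the
ratio of range-averaged means; both are computed and labeled because they
differ whenever the control trend is not flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def daily_living_mean(summaries: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-day mean and SEM of a metric over living, non-excluded flies.

    ``summaries`` is the concatenation of per-fly daily summaries (one
    group).  Returns a frame indexed by day with ``mean``, ``sem`` and
    ``n``; days with no living fly carry no row.  SEM is 0 by convention
    at n=1 (the n column flags it).
    """
    ok = summaries[(summaries["alive"]) & (~summaries["excluded"])]
    ok = ok.dropna(subset=[metric])
    if ok.empty:
        return pd.DataFrame(columns=["mean", "sem", "n"])
    g = ok.groupby("day")[metric]
    out = pd.DataFrame({"mean": g.mean(), "n": g.count()})
    sd = g.std(ddof=1)
    out["sem"] = np.where(out["n"] > 1, sd / np.sqrt(out["n"]), 0.0)
    return out[["mean", "sem", "n"]]


def relative_to_control(
    group: pd.DataFrame,
    control: pd.DataFrame,
    day_ranges: tuple[tuple[int, int], ...] = ((1, 12), (13, 20)),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group daily means as percent of control (control = 100%).

    Inputs are ``daily_living_mean`` outputs.  Returns the per-day percent
    series and a range-summary table with both conventions:
    ``mean_of_daily_ratios`` (average of per-day percentages) and
    ``ratio_of_means`` (100 x mean(group)/mean(control) over the range).
    Days where the control mean is zero are undefined and flagged.
    """
    days = group.index.intersection(control.index)
    g = group.loc[days, "mean"]
    c = control.loc[days, "mean"]
    pct = pd.DataFrame(index=days)
    pct["percent"] = np.where(c != 0, 100.0 * g / c, np.nan)
    pct["control_zero"] = c == 0

    rows = []
    for lo, hi in day_ranges:
        in_range = days[(days >= lo) & (days <= hi)]
        gr, cr = g.loc[in_range], c.loc[in_range]
        ratios = pct.loc[in_range, "percent"].dropna()
        rows.append(
            {
                "day_range": f"{lo}-{hi}",
                "mean_of_daily_ratios": float(ratios.mean()) if len(ratios) else np.nan,
                "ratio_of_means": float(100.0 * gr.mean() / cr.mean())
                if len(cr) and cr.mean() != 0
                else np.nan,
                "n_days": int(len(in_range)),
            }
        )
    return pct, pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    stars: str


def compare_groups(
    a, b, test: str = "t", pooled: bool = False
) -> ComparisonResult:
    """Two-sample comparison of per-fly values.

    ``test='t'``: two-tailed t-test, Welch by default (``pooled=True``
    for the classical equal-variance form).  ``test='mannwhitney'``:
    Mann-Whitney U, exact null when the combined sample size is at most
    20 and there are no ties, normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")

    if test in ("t", "welch"):
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                return ComparisonResult("t", 0.0, 1.0, "")
        res = sps.ttest_ind(a, b, equal_var=pooled)
        name = "t (pooled)" if pooled else "t (Welch)"
        return ComparisonResult(name, float(res.statistic), float(res.pvalue), significance_stars(res.pvalue))
    if test == "mannwhitney":
        method = "exact" if (a.size + b.size) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return ComparisonResult(
            f"mann-whitney ({method})",
            float(res.statistic),
            float(res.pvalue),
            significance_stars(res.pvalue),
        )
    raise ValueError(f"unknown test {test!r}")


@dataclass(frozen=True)
class BoxSummary:
    """Tukey boxplot statistics: median, quartiles, whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


def box_summary(values) -> BoxSummary:
    """Median, linear-interpolation quartiles and Tukey 1.5xIQR whiskers."""
    v = np.sort(np.asarray(pd.Series(values).dropna(), dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=int(v.size),
    )
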