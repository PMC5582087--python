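"""Quantify exercise success and the induced share of daily activity.

For each exercising cohort of the behavior run: per-fly mean success over
the 12 training days (percentage of the 90 daily stimuli answered with at
least one beam crossing), the group's boxplot statistics, and induced
activity as a share of the morning+evening peaks.
"""

import sys
from pathlib import Path

import pandas as pd

from damsleep import (
    StimulusSchedule,
    call_death,
    exercise_share,
    fly_mean_success,
    group_success_summary,
    read_monitor_file,
    to_activity_series,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    run = RESULTS / "run_behavior"
    truth = pd.read_csv(run / "truth.csv")
    tables = RESULTS / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    stimulus = StimulusSchedule()

    rows, means_by_group, share_by_group = [], {}, {}
    for mfile, part in truth.groupby("monitor_file", sort=False):
        if not part["exercising"].iloc[0]:
            continue
        table = read_monitor_file(run / str(mfile))
        for _, row in part.iterrows():
            series = to_activity_series(table, int(row["channel"]), fly_id=row["fly_id"])
            death = call_death(series)
            mean, _ = fly_mean_success(series, stimulus, death=death)
            share, _ = exercise_share(series, stimulus, death=death)
            rows.append(
                {"fly_id": row["fly_id"], "group": row["group"],
                 "mean_success_pct": mean, "share_pct": share,
                 "planted_p_resp": row["p_resp"]}
            )
            means_by_group.setdefault(row["group"], []).append(mean)
            share_by_group.setdefault(row["group"], []).append(share)

    per_fly = pd.DataFrame(rows)
    per_fly.to_csv(tables / "success_per_fly.csv", index=False)
    summary = []
    for group, means in means_by_group.items():
        stats = group_success_summary(means)
        planted = per_fly.loc[per_fly["group"] == group, "planted_p_resp"].iloc[0]
        shares = pd.Series(share_by_group[group]).dropna()
        summary.append(
            {"group": group, "planted_pct": 100 * planted, **stats,
             "mean_share_pct": float(shares.mean())}
        )
    summary = pd.DataFrame(summary).round(2)
    summary.to_csv(tables / "success_summary.csv", index=False)
    print("exercise success per group (planted vs recovered median [Q1-Q3]),")
    print("and induced share of morning+evening activity:")
    for _, r in summary.iterrows():
        print(
            f"  {r['group']:14s} planted {r['planted_pct']:5.2f}% -> "
            f"median {r['median']:5.2f}% [{r['q1']:5.2f}-{r['q3']:5.2f}], "
            f"share {r['mean_share_pct']:.1f}%"
        )
    return 0


if __name__ == "__main__":
    sys.exit(main())
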