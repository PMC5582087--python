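"""Score sleep, fragmentation and deaths for every fly of the behavior run.

Reads the DAM files written by 01_simulate.py, extracts each channel,
detects sleep bouts (5-min inactivity rule), calls deaths (>24 h terminal
immobility) and writes per-fly daily summaries, the bout table and the
death table under results/tables/.
"""

import sys
from pathlib import Path

import pandas as pd

from damsleep import (
    call_death,
    detect_sleep_bouts,
    read_monitor_file,
    summarize_daily,
    to_activity_series,
)
from damsleep.scoring import bouts_to_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    run = RESULTS / "run_behavior"
    truth = pd.read_csv(run / "truth.csv")
    tables = RESULTS / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    daily_frames, bout_frames, death_rows = [], [], []
    for mfile, part in truth.groupby("monitor_file", sort=False):
        table = read_monitor_file(run / str(mfile))
        for _, row in part.iterrows():
            series = to_activity_series(table, int(row["channel"]), fly_id=row["fly_id"])
            bouts = detect_sleep_bouts(series)
            death = call_death(series)
            summary = summarize_daily(series, bouts, death)
            summary.insert(1, "group", row["group"])
            daily_frames.append(summary)
            bf = bouts_to_frame(series.fly_id, bouts)
            bf.insert(1, "group", row["group"])
            bout_frames.append(bf)
            death_rows.append(
                {
                    "fly_id": series.fly_id,
                    "group": row["group"],
                    "event": death.event,
                    "death_day": death.days_since(series.start) if death.event else None,
                }
            )

    daily = pd.concat(daily_frames, ignore_index=True)
    bouts = pd.concat(bout_frames, ignore_index=True)
    deaths = pd.DataFrame(death_rows)
    daily.to_csv(tables / "daily.csv", index=False)
    bouts.to_csv(tables / "bouts.csv", index=False)
    deaths.to_csv(tables / "deaths_behavior.csv", index=False)

    ok = daily[daily["alive"] & ~daily["excluded"]]
    per_group = ok.groupby("group")[["activity", "sleep", "sleep_short"]].mean().round(1)
    print("mean per living fly-day (counts / sleep min / fragmented-sleep min):")
    print(per_group.to_string())
    frag_share = (ok.groupby("group")["sleep_short"].sum() / ok.groupby("group")["sleep"].sum())
    print("\nshort-bout share of sleep per group:")
    print((100 * frag_share).round(1).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
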