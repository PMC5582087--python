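"""Render representative actograms and average daily activity profiles.

One actogram per cohort (channel 1), with the yellow/gray light-dark bar
and a red frame over the ZT7 exercise window on training days, plus
group-average 288-bin daily profiles split into the training (days 1-12)
and post-training (days 13-20) windows.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from damsleep import (
    StimulusSchedule,
    actogram_matrix,
    call_death,
    daily_profile,
    read_monitor_file,
    render_actogram,
    to_activity_series,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    run = RESULTS / "run_behavior"
    truth = pd.read_csv(run / "truth.csv")
    figures = RESULTS / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    stimulus = StimulusSchedule()

    profiles = {}
    for mfile, part in truth.groupby("monitor_file", sort=False):
        table = read_monitor_file(run / str(mfile))
        group = part["group"].iloc[0]
        exercising = bool(part["exercising"].iloc[0])
        series_list, deaths = [], []
        for _, row in part.iterrows():
            s = to_activity_series(table, int(row["channel"]), fly_id=row["fly_id"])
            series_list.append(s)
            d = call_death(s)
            deaths.append(
                int(d.days_since(s.start)) + 1 if d.event else None
            )
        mat = actogram_matrix(series_list[0], exercise=stimulus if exercising else None)
        render_actogram(
            mat, series_list[0].schedule, stimulus if exercising else None,
            figures / f"actogram_{group}.png",
        )
        profiles[group] = {
            rng: daily_profile(series_list, day_range=rng, death_days=deaths)
            for rng in ((1, 12), (13, 20))
        }

    zt = np.arange(288) * 5 / 60
    for rng_key, suffix in (((1, 12), "days01-12"), ((13, 20), "days13-20")):
        fig, ax = plt.subplots(figsize=(7, 4))
        for group in ("wt-ex", "ad-ex", "wt-ctrl", "ad-ctrl"):
            ax.plot(zt, profiles[group][rng_key], lw=1.0, label=group)
        ax.axvspan(7.0, 7.5, color="red", alpha=0.15)
        ax.set_xlabel("ZT (h)")
        ax.set_ylabel("counts / 5 min")
        ax.set_title(f"average daily profile, {suffix}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(figures / f"daily_profile_{suffix}.png", dpi=150)
        plt.close(fig)
    print(f"wrote {len(profiles)} actograms and 2 profile figures -> {figures}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
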