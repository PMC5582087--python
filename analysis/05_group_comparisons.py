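"""Group comparisons: relative metrics vs controls and episode sleep effects.

From the scored daily table: (a) AD-like activity, sleep and fragmented
(short-bout) sleep relative to each control genotype, summarized over the
training window (days 1-12) and the post-training window (days 13-20)
under both range conventions; (b) per-episode sleep (night, morning,
siesta, evening) of exercising vs non-exercising arms with two-tailed
Welch t-tests and star annotations.
"""

import sys
from pathlib import Path

import pandas as pd

from damsleep import compare_groups, daily_living_mean, relative_to_control

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    tables = RESULTS / "tables"
    daily = pd.read_csv(tables / "daily.csv")

    series = {
        g: {m: daily_living_mean(daily[daily["group"] == g], m)
            for m in ("activity", "sleep", "sleep_short")}
        for g in daily["group"].unique()
    }

    rel_rows = []
    for control in ("wt-ctrl", "driver-ctrl", "reporter-ctrl"):
        for metric in ("activity", "sleep", "sleep_short"):
            _, ranges = relative_to_control(
                series["ad-ctrl"][metric], series[control][metric]
            )
            for _, r in ranges.iterrows():
                rel_rows.append(
                    {"metric": metric, "control": control, **r.to_dict()}
                )
    rel = pd.DataFrame(rel_rows).round(1)
    rel.to_csv(tables / "relative_to_controls.csv", index=False)
    print("AD-like relative to controls (100% = control), ratio-of-means:")
    print(
        rel.pivot_table(index=["metric", "day_range"], columns="control",
                        values="ratio_of_means").round(1).to_string()
    )

    ep_rows = []
    print("\nexercise effect on episode sleep (ex vs ctrl, Welch t):")
    for short in ("wt", "driver", "reporter", "ad"):
        for episode in ("night", "morning", "siesta", "evening"):
            col = f"sleep_{episode}"
            sub = daily[daily["alive"] & ~daily["excluded"] & (daily["day"] <= 12)]
            ex = sub[sub["group"] == f"{short}-ex"].groupby("fly_id")[col].mean()
            ctrl = sub[sub["group"] == f"{short}-ctrl"].groupby("fly_id")[col].mean()
            res = compare_groups(ex, ctrl, test="t")
            ep_rows.append(
                {"genotype": short, "episode": episode,
                 "ex_mean_min": ex.mean(), "ctrl_mean_min": ctrl.mean(),
                 "t": res.statistic, "p": res.p_value, "stars": res.stars}
            )
            if res.stars:
                print(
                    f"  {short:8s} {episode:8s}: {ex.mean():6.1f} vs {ctrl.mean():6.1f} min"
                    f"  p={res.p_value:.2g} {res.stars}"
                )
    pd.DataFrame(ep_rows).round(3).to_csv(tables / "episode_sleep_tests.csv", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
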