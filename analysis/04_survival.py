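"""Survival analysis of the 40-day run: KM curves, medians, log-rank.

Death calls use the >24 h terminal-immobility rule on the written DAM
files; per group a Kaplan-Meier curve and its median are computed, the
exercising vs non-exercising arm of each genotype is compared with the
log-rank (Mantel-Cox) test, and the AD-like median prolongation is
reported as difference and percent.
"""

import sys
from pathlib import Path

import pandas as pd

from damsleep import (
    call_death,
    km_estimate,
    logrank_test,
    median_prolongation,
    plot_km,
    read_monitor_file,
    record_from_death,
    to_activity_series,
)
from damsleep.survival import curve_to_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    run = RESULTS / "run_survival"
    truth = pd.read_csv(run / "truth.csv")
    tables = RESULTS / "tables"
    figures = RESULTS / "figures"
    tables.mkdir(parents=True, exist_ok=True)
    figures.mkdir(parents=True, exist_ok=True)

    records = {}
    for mfile, part in truth.groupby("monitor_file", sort=False):
        table = read_monitor_file(run / str(mfile))
        for _, row in part.iterrows():
            series = to_activity_series(table, int(row["channel"]), fly_id=row["fly_id"])
            death = call_death(series)
            records.setdefault(row["group"], []).append(
                record_from_death(series, death, row["group"])
            )

    curves = {g: km_estimate(rs) for g, rs in sorted(records.items())}
    medians = pd.DataFrame(
        [{"group": g, "median_days": c.median, "n": c.n_subjects,
          "events": int(c.n_events.sum())} for g, c in curves.items()]
    )
    medians.to_csv(tables / "km_medians.csv", index=False)
    for g, c in curves.items():
        curve_to_frame(c).to_csv(tables / f"km_{g}.csv", index=False)

    print("KM median survival (days) per group:")
    print(medians.round(2).to_string(index=False))

    tests = []
    for short in ("wt", "driver", "reporter", "ad"):
        res = logrank_test(records[f"{short}-ex"], records[f"{short}-ctrl"])
        tests.append({"genotype": short, "chi2": res.statistic, "p": res.p_value})
        print(f"log-rank {short}-ex vs {short}-ctrl: chi2={res.statistic:.2f} p={res.p_value:.2g}")
    pd.DataFrame(tests).to_csv(tables / "logrank.csv", index=False)

    m = medians.set_index("group")["median_days"]
    diff, pct = median_prolongation(m["ad-ex"], m["ad-ctrl"])
    print(f"AD-like exercise prolongation: {diff:.1f} days ({pct:.1f}%)")

    plot_km({k: curves[k] for k in ("ad-ex", "ad-ctrl")}, figures / "km_ad.png",
            colors={"ad-ex": "red", "ad-ctrl": "black"})
    plot_km(curves, figures / "km_all.png")
    return 0


if __name__ == "__main__":
    sys.exit(main())
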