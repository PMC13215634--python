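#!/usr/bin/env python
"""Aggregate detected bouts and self-report logs into the outcome measures.

Produces per-participant daily series for both sources (scratch/) and the
aggregated outcomes — cumulative minutes, average daily minutes, days
worn — side by side per source (results/wear_summaries.csv).
"""

from pathlib import Path

import pandas as pd

from bracewear import io
from bracewear.aggregate import daily_minutes, summarize

ROOT = Path(__file__).resolve().parents[1]
WINDOW = pd.date_range("2024-01-01", periods=42, freq="D")


def main() -> None:
    intervals = io.read_intervals_csv(ROOT / "scratch" / "intervals.csv")
    selfreport = io.read_selfreport_csv(ROOT / "scratch" / "cohort" / "selfreport.csv", WINDOW)

    sensor_daily = {pid: daily_minutes(ivs, WINDOW, pid) for pid, ivs in intervals.items()}
    io.write_daily_csv(sensor_daily, ROOT / "scratch" / "sensor_daily.csv")
    io.write_daily_csv(selfreport, ROOT / "scratch" / "selfreport_daily.csv")

    rows = []
    for pid in sorted(sensor_daily):
        s = summarize(sensor_daily[pid])
        r = summarize(selfreport[pid])
        rows.append(
            {
                "participant_id": pid,
                "sensor_avg_daily": round(s.avg_daily_minutes, 1),
                "selfreport_avg_daily": round(r.avg_daily_minutes, 1),
                "sensor_days_worn": s.days_worn,
                "selfreport_days_worn": r.days_worn,
                "selfreport_days_observed": r.days_observed,
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "wear_summaries.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))

    over_min = (table["selfreport_avg_daily"] > table["sensor_avg_daily"]).sum()
    over_days = (table["selfreport_days_worn"] > table["sensor_days_worn"]).sum()
    print(
        f"\n{over_min}/10 participants over-report average daily minutes; "
        f"{over_days}/10 over-report days worn. Table: {out}"
    )


if __name__ == "__main__":
    main()
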