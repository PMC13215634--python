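#!/usr/bin/env python
"""Detect donning/doffing bouts from the simulated sensor traces.

Reads scratch/cohort/sensor.csv (written by 01_simulate_cohort.py), runs
the gradient detector, writes the detected intervals to scratch/ and a
per-participant comparison against ground truth to results/.
"""

from pathlib import Path

import pandas as pd

from bracewear import io
from bracewear.detect import detect_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    series = io.read_sensor_csv(ROOT / "scratch" / "cohort" / "sensor.csv")
    truth = io.read_truth_json(ROOT / "scratch" / "cohort" / "truth.json")

    intervals = detect_cohort(series)
    io.write_intervals_csv(intervals, ROOT / "scratch" / "intervals.csv")

    rows = []
    for pid, ivs in sorted(intervals.items()):
        detected_min = sum(iv.duration_minutes for iv in ivs)
        true_min = sum(truth[pid]["daily_minutes"].values())
        rows.append(
            {
                "participant_id": pid,
                "detected_bouts": len(ivs),
                "true_bouts": len(truth[pid]["intervals"]),
                "detected_minutes": round(detected_min, 1),
                "true_minutes": round(true_min, 1),
                "error_minutes": round(detected_min - true_min, 1),
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "detection_overview.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    mean_abs = table["error_minutes"].abs().mean()
    print(
        f"\nDetected {table['detected_bouts'].sum()} bouts vs {table['true_bouts'].sum()} true; "
        f"mean |total error| {mean_abs:.1f} min over 42 days "
        f"({mean_abs / 42:.2f} min/day). Table: {out}"
    )


if __name__ == "__main__":
    main()
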