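#!/usr/bin/env python
"""Monte-Carlo validation of the wear detector against ground truth.

Measures daily-wear recovery error under noise-free and noisy sensor
conditions, false-positive wear on never-worn records, and the effect of
ambient "hot car" confounder steps with and without a discriminating
plateau threshold.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from bracewear.aggregate import daily_minutes
from bracewear.config import DetectConfig, SimConfig
from bracewear.detect import detect_wear
from bracewear.simulate import simulate_temperature, simulate_wear_schedule

ROOT = Path(__file__).resolve().parents[1]


def run_condition(n_seeds, base_seed, sim_updates, detect_cfg, wear=True):
    errors = []
    for k in range(n_seeds):
        cfg = SimConfig(n_participants=1, n_days=42, seed=base_seed + k, **sim_updates)
        schedule = simulate_wear_schedule(cfg, 0) if wear else []
        if not wear:
            cfg = cfg.model_copy(update={"p_wear_day": 0.0, "p_wear_day_between_sd": 0.0})
        series, truth = simulate_temperature(schedule, cfg, 0)
        window = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
        det = daily_minutes(detect_wear(series, detect_cfg), window).minutes
        errors.extend(np.abs(det.to_numpy() - truth.daily.minutes.to_numpy()))
    return float(np.mean(errors))


def main(seed: int = 1) -> None:
    default = DetectConfig()
    strict_plateau = DetectConfig(plateau_rise=7.5)
    rows = [
        (
            "noise-free, no confounders (MAE)",
            run_condition(20, seed, dict(sensor_noise_sd=0.0, confounder_rate=0.0), default),
        ),
        (
            "default noise, no confounders (MAE)",
            run_condition(20, seed + 1000, dict(confounder_rate=0.0), default),
        ),
        (
            "default noise + confounders (MAE)",
            run_condition(20, seed + 2000, dict(), default),
        ),
        (
            "default noise + confounders, plateau_rise=7.5 (MAE)",
            run_condition(20, seed + 2000, dict(), strict_plateau),
        ),
        (
            "no wear, default noise (false positive)",
            run_condition(20, seed + 3000, dict(confounder_rate=0.0), default, wear=False),
        ),
        (
            "no wear, confounders (false positive)",
            run_condition(20, seed + 4000, dict(), default, wear=False),
        ),
        (
            "no wear, confounders, plateau_rise=7.5 (false positive)",
            run_condition(20, seed + 4000, dict(), strict_plateau, wear=False),
        ),
    ]
    table = pd.DataFrame(rows, columns=["condition", "min_per_day"])
    table["min_per_day"] = table["min_per_day"].round(2)
    out = ROOT / "results" / "detection_validation.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(
        "\nGradient detection recovers daily wear to within a few minutes per day; "
        "ambient +8 degC steps are the dominant false-positive source and are "
        "suppressed by a plateau-rise threshold above the step amplitude. "
        f"Table: {out}"
    )


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    main(parser.parse_args().seed)
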