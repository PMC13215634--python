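"""End-to-end orchestration: simulate -> detect -> aggregate -> agree -> sensitivity."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import aggregate, agreement, detect, io, plots, sensitivity, simulate
from .config import DetectConfig, SimConfig

log = logging.getLogger("bracewear")


class RunConfig(BaseModel):
    out_dir: str
    sim: SimConfig | None = None
    sensor_csv: str | None = None
    selfreport_csv: str | None = None
    detect: DetectConfig = Field(default_factory=DetectConfig)
    levels: list[str] = Field(default_factory=lambda: list(agreement.LEVELS))
    n_boot: int = 2000
    seed: int = 0
    make_plots: bool = True

    def model_post_init(self, __context) -> None:
        unknown = set(self.levels) - set(agreement.LEVELS)
        if unknown:
            raise ValueError(f"unknown levels: {sorted(unknown)}")
        if self.sim is None and (self.sensor_csv is None or self.selfreport_csv is None):
            raise ValueError("provide either a SimConfig or sensor + self-report CSV paths")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write results, figures and a manifest.

    Deterministic for a fixed config: identical runs produce identical
    result files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        log.info("simulating cohort: %d participants x %d days", config.sim.n_participants, config.sim.n_days)
        cohort = simulate.simulate_cohort(config.sim)
        io.write_cohort(cohort, out / "data")
        sensor_series = cohort.temperature
        window = pd.date_range(config.sim.start_date, periods=config.sim.n_days, freq="D")
        selfreport = cohort.selfreport
    else:
        log.info("reading sensor data from %s", config.sensor_csv)
        sensor_series = io.read_sensor_csv(config.sensor_csv)
        dates = sorted({t.normalize() for s in sensor_series.values() for t in s.timestamps})
        window = pd.date_range(dates[0], dates[-1], freq="D")
        selfreport = io.read_selfreport_csv(config.selfreport_csv, window)

    log.info("detecting wear bouts")
    intervals = detect.detect_cohort(sensor_series, config.detect)
    io.write_intervals_csv(intervals, out / "intervals.csv")

    log.info("aggregating daily wear")
    sensor_daily = {
        pid: aggregate.daily_minutes(ivs, window, pid) for pid, ivs in intervals.items()
    }
    io.write_daily_csv(sensor_daily, out / "sensor_daily.csv")
    io.write_daily_csv(selfreport, out / "selfreport_daily.csv")

    summaries = []
    for pid in sorted(sensor_daily):
        for source, daily in (("sensor", sensor_daily[pid]), ("selfreport", selfreport.get(pid))):
            if daily is None or daily.observed.empty:
                continue
            s = aggregate.summarize(daily)
            summaries.append(
                {
                    "participant_id": pid,
                    "source": source,
                    "total_minutes": s.total_minutes,
                    "avg_daily_minutes": s.avg_daily_minutes,
                    "days_worn": s.days_worn,
                    "days_observed": s.days_observed,
                }
            )
    pd.DataFrame(summaries).to_csv(out / "summaries.csv", index=False)

    log.info("agreement at levels: %s", ", ".join(config.levels))
    report = sensitivity.sensitivity_suite(
        sensor_daily,
        selfreport,
        window=window,
        levels=config.levels,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    results = report.to_dict()
    (out / "agreement.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    pd.DataFrame(
        [est for ests in report.scenarios.values() for est in (e.to_dict() for e in ests.values())],
        index=pd.MultiIndex.from_tuples(
            [(name, lvl) for name, ests in report.scenarios.items() for lvl in ests],
            names=["scenario", "level"],
        ),
    ).to_csv(out / "agreement.csv")

    if config.make_plots:
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for level in config.levels:
            try:
                panel = agreement.build_panel(sensor_daily, selfreport, level)
            except Exception:  # plotting is best-effort
                continue
            plots.equality_scatter(panel, figdir / f"scatter_{level}.png", level)
        plots.trajectory_plot(sensor_daily, selfreport, figdir / "trajectories.png")

    row_counts = {
        "participants": len(sensor_daily),
        "intervals": sum(len(v) for v in intervals.values()),
        "days": int(sum(len(d.minutes) for d in sensor_daily.values())),
    }
    cfg_dict = config.model_dump()
    io.write_manifest(out / "manifest.json", cfg_dict, config.seed, row_counts)
    log.info("pipeline complete: results in %s", out)
    return results
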