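"""CSV/JSON readers and writers for every pipeline artifact.

Dialect: comma-separated UTF-8 with a mandatory header row.  Sensor rows
are (participant_id, timestamp ISO-8601 local, temp_c with one decimal);
self-report rows are (participant_id, date ISO-8601, minutes) and an
absent (participant, date) row within the study window is a missing log
entry, not a zero.  Timestamps are naive local time; a timezone suffix is
accepted but stripped with a warning.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    DailyWearSeries,
    InputError,
    SimTruth,
    TemperatureSeries,
    WearInterval,
)

SENSOR_COLUMNS = ["participant_id", "timestamp", "temp_c"]
SELFREPORT_COLUMNS = ["participant_id", "date", "minutes"]
INTERVAL_COLUMNS = ["participant_id", "don", "doff", "minutes"]


def write_sensor_csv(series_by_pid: dict[str, TemperatureSeries], path) -> None:
    frames = [series_by_pid[pid].to_frame() for pid in sorted(series_by_pid)]
    df = pd.concat(frames, ignore_index=True)
    df["temp_c"] = df["temp_c"].map(lambda v: f"{v:.1f}")
    df.to_csv(path, index=False)


def read_sensor_csv(path) -> dict[str, TemperatureSeries]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if list(df.columns) != SENSOR_COLUMNS:
        raise InputError(f"{path}: expected header {SENSOR_COLUMNS}, got {list(df.columns)}")
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: malformed timestamp ({exc})") from exc
    if getattr(stamps.dt, "tz", None) is not None:
        warnings.warn(f"{path}: timezone information ignored (naive local time assumed)", stacklevel=2)
        stamps = stamps.dt.tz_localize(None)
    temps = pd.to_numeric(df["temp_c"], errors="coerce")
    if temps.isna().any():
        line = int(temps.index[temps.isna()][0]) + 2  # header is line 1
        raise InputError(f"{path}: malformed temp_c at line {line}")
    df = df.assign(timestamp=stamps, temp_c=temps)
    out: dict[str, TemperatureSeries] = {}
    for pid, g in df.groupby("participant_id", sort=True):
        dup = g["timestamp"].duplicated()
        if dup.any():
            line = int(g.index[dup][0]) + 2
            raise InputError(f"{path}: duplicated timestamp for {pid} at line {line}")
        g = g.sort_values("timestamp")
        out[pid] = TemperatureSeries(pid, pd.DatetimeIndex(g["timestamp"]), g["temp_c"].to_numpy())
    return out


def write_selfreport_csv(logs: dict[str, DailyWearSeries], path) -> None:
    rows = []
    for pid in sorted(logs):
        for date, minutes in logs[pid].observed.items():
            rows.append((pid, date.date().isoformat(), int(round(minutes))))
    pd.DataFrame(rows, columns=SELFREPORT_COLUMNS).to_csv(path, index=False)


def read_selfreport_csv(path, window) -> dict[str, DailyWearSeries]:
    """Read daily logs; absent in-window dates become missing entries."""
    if isinstance(window, pd.DatetimeIndex):
        index = window.normalize()
    else:
        start, end = window
        index = pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize(), freq="D")
    df = pd.read_csv(path, dtype={"participant_id": str})
    if list(df.columns) != SELFREPORT_COLUMNS:
        raise InputError(f"{path}: expected header {SELFREPORT_COLUMNS}, got {list(df.columns)}")
    minutes = pd.to_numeric(df["minutes"], errors="coerce")
    if minutes.isna().any():
        line = int(minutes.index[minutes.isna()][0]) + 2
        raise InputError(f"{path}: malformed minutes at line {line}")
    if (minutes < 0).any():
        raise InputError(f"{path}: negative minutes")
    if (minutes > 1440).any():
        raise InputError(f"{path}: minutes exceed 1440 in a day")
    df = df.assign(date=pd.to_datetime(df["date"]).dt.normalize(), minutes=minutes)
    out: dict[str, DailyWearSeries] = {}
    for pid, g in df.groupby("participant_id", sort=True):
        if g["date"].duplicated().any():
            raise InputError(f"{path}: duplicate date for {pid}")
        s = g.set_index("date")["minutes"].astype(float).reindex(index)
        out[pid] = DailyWearSeries(pid, s)
    return out


def write_intervals_csv(intervals_by_pid: dict[str, list[WearInterval]], path) -> None:
    rows = [
        (pid, iv.don.isoformat(), iv.doff.isoformat(), round(iv.duration_minutes, 3))
        for pid in sorted(intervals_by_pid)
        for iv in intervals_by_pid[pid]
    ]
    pd.DataFrame(rows, columns=INTERVAL_COLUMNS).to_csv(path, index=False)


def read_intervals_csv(path) -> dict[str, list[WearInterval]]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if list(df.columns) != INTERVAL_COLUMNS:
        raise InputError(f"{path}: expected header {INTERVAL_COLUMNS}, got {list(df.columns)}")
    out: dict[str, list[WearInterval]] = {}
    for pid, g in df.groupby("participant_id", sort=True):
        out[pid] = sorted(
            WearInterval(pd.Timestamp(d), pd.Timestamp(f)) for d, f in zip(g["don"], g["doff"])
        )
    return out


def write_daily_csv(dailies: dict[str, DailyWearSeries], path) -> None:
    rows = []
    for pid in sorted(dailies):
        for date, minutes in dailies[pid].minutes.items():
            val = "NA" if pd.isna(minutes) else round(float(minutes), 3)
            rows.append((pid, date.date().isoformat(), val))
    pd.DataFrame(rows, columns=["participant_id", "date", "minutes_or_NA"]).to_csv(path, index=False)


def read_daily_csv(path) -> dict[str, DailyWearSeries]:
    df = pd.read_csv(path, dtype={"participant_id": str}, na_values=["NA"])
    out: dict[str, DailyWearSeries] = {}
    for pid, g in df.groupby("participant_id", sort=True):
        s = g.assign(date=pd.to_datetime(g["date"])).set_index("date")["minutes_or_NA"].astype(float)
        out[pid] = DailyWearSeries(pid, s)
    return out


def write_truth_json(truths: dict[str, SimTruth], path) -> None:
    payload = {
        pid: {
            "intervals": [[iv.don.isoformat(), iv.doff.isoformat()] for iv in t.intervals],
            "daily_minutes": {
                d.date().isoformat(): float(m) for d, m in t.daily.minutes.items()
            },
        }
        for pid, t in truths.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> dict[str, dict]:
    return json.loads(Path(path).read_text())


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sensor": out_dir / "sensor.csv",
        "selfreport": out_dir / "selfreport.csv",
        "truth": out_dir / "truth.json",
    }
    write_sensor_csv(cohort.temperature, paths["sensor"])
    write_selfreport_csv(cohort.selfreport, paths["selfreport"])
    write_truth_json(cohort.truth, paths["truth"])
    return paths


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config_dict: dict, seed: int | None, row_counts: dict[str, int]) -> None:
    import bracewear

    manifest = {
        "config_hash": config_hash(config_dict),
        "config": json.loads(json.dumps(config_dict, default=str)),
        "seed": seed,
        "versions": {
            "bracewear": bracewear.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": row_counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
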