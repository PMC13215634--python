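"""Gradient-based donning/doffing detection from sensor temperature traces.

A donning event is a sharp temperature spike — a run of at most
``confirm_samples`` consecutive positive first differences whose sum
reaches ``theta_on`` — and a doffing event the analogous drop.  Working on
first differences rather than absolute levels makes the detector invariant
to ambient temperature offsets and slow diurnal drift.  Events are paired
into bouts by a NOT-WORN/WORN state machine with boundary rules for bouts
open at either end of the record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DetectConfig
from .types import InputError, TemperatureSeries, WearInterval

DON = "DON"
DOFF = "DOFF"


@dataclass(frozen=True)
class Event:
    instant: pd.Timestamp
    kind: str
    index: int  # sample index of the first sample of the triggering run


def first_difference(series: TemperatureSeries) -> np.ndarray:
    """Per-sample temperature change; element i = temps[i+1] - temps[i]."""
    if len(series) < 2:
        raise InputError("need at least 2 samples for a gradient")
    return np.diff(series.temps)


def _triggers(diffs: np.ndarray, theta: float, confirm: int) -> np.ndarray:
    """Indices i where a run of <= confirm positive diffs starting at i sums to >= theta."""
    pos = diffs > 0
    hit = np.zeros(len(diffs), dtype=bool)
    run_sum = np.zeros(len(diffs))
    run_ok = pos.copy()
    run_sum[pos] = diffs[pos]
    hit |= run_ok & (run_sum >= theta)
    for w in range(2, confirm + 1):
        run_ok[: len(diffs) - (w - 1)] &= pos[w - 1 :]
        run_sum[: len(diffs) - (w - 1)] += np.where(pos[w - 1 :], diffs[w - 1 :], 0.0)
        run_ok[len(diffs) - (w - 1) :] = False
        hit |= run_ok & (run_sum >= theta)
    return np.flatnonzero(hit)


def detect_events(series: TemperatureSeries, config: DetectConfig) -> list[Event]:
    """Spike (DON) and drop (DOFF) events, each stamped at the first sample
    of its triggering run."""
    diffs = first_difference(series)
    don_idx = _triggers(diffs, config.theta_on, config.confirm_samples)
    doff_idx = _triggers(-diffs, config.theta_off, config.confirm_samples)
    events = [Event(series.timestamps[i], DON, int(i)) for i in don_idx]
    events += [Event(series.timestamps[i], DOFF, int(i)) for i in doff_idx]
    events.sort(key=lambda e: (e.instant, e.kind))  # DOFF before DON on ties
    return events


def _plateau_ok(series: TemperatureSeries, don_idx: int, doff_idx: int, config: DetectConfig) -> bool:
    """Sanity check: donning must be followed by a sustained warm plateau.

    Within the first ``plateau_window`` in-bout samples there must be a run
    of consecutive samples at least ``plateau_rise`` above the pre-don
    level (run length ``plateau_samples``, shortened for bouts briefer than
    that).  Sensor noise cannot sustain such a rise, so noise-triggered
    donning events are cancelled instead of opening runaway bouts; with a
    rise threshold above the ambient-step amplitude the same check rejects
    hot-car transients, which can never lift the trace by more than the
    step itself, while skin contact keeps driving it toward skin
    temperature.
    """
    base = series.temps[don_idx]
    window_end = min(doff_idx, don_idx + config.plateau_window)
    segment = series.temps[don_idx + 1 : window_end + 1]
    need = min(config.plateau_samples, len(segment))
    if need == 0:
        return False
    run = 0
    for hot in segment >= base + config.plateau_rise:
        run = run + 1 if hot else 0
        if run >= need:
            return True
    return False


def pair_events(
    events: list[Event],
    series: TemperatureSeries,
    config: DetectConfig,
    start: int = 0,
    stop: int | None = None,
) -> list[WearInterval]:
    """Pair alternating events into bouts over samples [start, stop).

    State machine from NOT-WORN: a DON opens, the next DOFF closes; repeat
    DONs while worn and DOFFs while not worn are ignored — except a DOFF
    that is the very first event, which closes a bout open at the record
    start; a bout still open at the record end closes at the last sample.
    Bouts shorter than ``min_bout`` are dropped, then bouts separated by
    at most ``merge_gap`` are merged.
    """
    stop = len(series) if stop is None else stop
    first_ts = series.timestamps[start]
    last_ts = series.timestamps[stop - 1]

    raw: list[tuple[pd.Timestamp, int, pd.Timestamp, int]] = []
    worn = False
    open_ts: pd.Timestamp | None = None
    open_idx = start
    for k, ev in enumerate(events):
        if ev.kind == DON:
            if not worn:
                worn, open_ts, open_idx = True, ev.instant, ev.index
        else:
            if worn:
                if ev.instant > open_ts:
                    raw.append((open_ts, open_idx, ev.instant, ev.index))
                worn = False
            elif k == 0 and ev.instant > first_ts:
                raw.append((first_ts, start, ev.instant, ev.index))
    if worn and last_ts > open_ts:
        raw.append((open_ts, open_idx, last_ts, stop - 1))

    if config.plateau_check:
        # bouts already open at the record start have no rise to confirm
        raw = [b for b in raw if b[1] == start or _plateau_ok(series, b[1], b[3], config)]

    bouts = [
        WearInterval(don, doff)
        for don, _, doff, _ in raw
        if (doff - don).total_seconds() / 60.0 >= config.min_bout
    ]

    merged: list[WearInterval] = []
    for bout in bouts:
        if merged and (bout.don - merged[-1].doff).total_seconds() / 60.0 <= config.merge_gap:
            merged[-1] = WearInterval(merged[-1].don, bout.doff)
        else:
            merged.append(bout)
    return merged


def detect_wear(series: TemperatureSeries, config: DetectConfig | None = None) -> list[WearInterval]:
    """Full detector: gradient -> events -> paired bouts.

    The series is split at any sampling gap larger than
    ``gap_split_factor`` x the sampling interval and each contiguous
    segment is processed independently, so outages never produce spurious
    gradients or bouts bridging a gap.
    """
    config = config or DetectConfig()
    if config.min_bout < series.sampling_interval_minutes:
        raise InputError("min_bout must be at least the sampling interval")
    intervals: list[WearInterval] = []
    for seg in series.segments(config.gap_split_factor):
        if seg.stop - seg.start < 2:
            continue
        sub = TemperatureSeries(series.participant_id, series.timestamps[seg], series.temps[seg])
        events = detect_events(sub, config)
        offset = seg.start
        events = [Event(e.instant, e.kind, e.index + offset) for e in events]
        intervals.extend(pair_events(events, series, config, start=seg.start, stop=seg.stop))
    return sorted(intervals)


def detect_cohort(
    cohort_series: dict[str, TemperatureSeries], config: DetectConfig | None = None
) -> dict[str, list[WearInterval]]:
    return {pid: detect_wear(s, config) for pid, s in cohort_series.items()}
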