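"""Synthetic cohort generator: wear schedules, temperature traces, self-report.

The thermal model is first-order Newtonian relaxation: while the brace is
worn the sensor relaxes toward skin temperature with time constant
``tau_on``; off the body it relaxes toward ambient (a diurnal sinusoid,
optionally perturbed by transient "hot car" confounder steps) with
``tau_off``.  Gaussian sensor noise is added and the result quantized to
the sensor's precision.  Every participant draws from an independent named
RNG substream, so resizing the cohort never changes earlier participants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import daily_minutes
from .config import SimConfig
from .types import Cohort, DailyWearSeries, SimTruth, TemperatureSeries, WearInterval

_STREAM_SCHEDULE = 0
_STREAM_TEMPERATURE = 1
_STREAM_REPORT = 2

# bouts start between 07:00 and 21:00; the trial gives no time-of-day
# distribution, so this is a plausibility choice
_EARLIEST_START_MIN = 7 * 60
_LATEST_START_MIN = 21 * 60


def _rng(config: SimConfig, participant_index: int, stream: int) -> np.random.Generator:
    """Named substream: (participant, stream) keyed off the master seed."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(participant_index, stream))
    return np.random.default_rng(ss)


def participant_id(index: int) -> str:
    return f"P{index + 1:02d}"


def round_to(step: float, x: float) -> float:
    """Round half away from zero to the nearest multiple of ``step``."""
    if step <= 0:
        raise ValueError("rounding step must be positive")
    return float(np.floor(abs(x) / step + 0.5) * step * np.sign(x))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def simulate_wear_schedule(config: SimConfig, participant_index: int) -> list[WearInterval]:
    """Draw one participant's true don->doff schedule over the study window.

    Each day carries at most one bout (probability ``p_wear_day``), with
    duration from a truncated normal (floor = one sampling interval) in
    whole minutes.  Participant-level propensity and typical bout length
    vary across the cohort via the ``*_between_sd`` settings.  Bouts are
    truncated at 23:59 unless midnight spanning is enabled.
    """
    rng = _rng(config, participant_index, _STREAM_SCHEDULE)
    p_i = float(np.clip(config.p_wear_day + config.p_wear_day_between_sd * rng.standard_normal(), 0.0, 1.0))
    mu_i = max(
        float(config.sampling_interval),
        config.bout_minutes_mean + config.bout_mean_between_sd * rng.standard_normal(),
    )

    start_ts = pd.Timestamp(config.start_date)
    intervals: list[WearInterval] = []
    for day in range(config.n_days):
        if rng.random() >= p_i:
            continue
        duration = round(_truncated_normal(rng, mu_i, config.bout_minutes_sd, config.sampling_interval))
        duration = max(duration, config.sampling_interval)
        start_min = int(rng.integers(_EARLIEST_START_MIN, _LATEST_START_MIN + 1))
        end_min = start_min + duration
        if not config.allow_midnight_spanning:
            end_min = min(end_min, 1439)
        don = start_ts + pd.Timedelta(minutes=day * 1440 + start_min)
        doff = start_ts + pd.Timedelta(minutes=day * 1440 + end_min)
        intervals.append(WearInterval(don, doff))
    return intervals


def _ambient(config: SimConfig, minute_of_day: np.ndarray) -> np.ndarray:
    """Diurnal ambient sinusoid peaking mid-afternoon (15:00)."""
    return config.t_ambient_mean + config.ambient_diurnal_amp * np.sin(
        2 * np.pi * (minute_of_day - 540.0) / 1440.0
    )


def _wear_mask(intervals: list[WearInterval], start_ts: pd.Timestamp, minutes: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(minutes), dtype=bool)
    for iv in intervals:
        a = (iv.don - start_ts).total_seconds() / 60.0
        b = (iv.doff - start_ts).total_seconds() / 60.0
        lo = int(np.searchsorted(minutes, a, side="left"))
        hi = int(np.searchsorted(minutes, b, side="left"))  # half-open [don, doff)
        mask[lo:hi] = True
    return mask


def _confounder_offsets(
    config: SimConfig,
    rng: np.random.Generator,
    intervals: list[WearInterval],
    start_ts: pd.Timestamp,
    minutes: np.ndarray,
) -> np.ndarray:
    offsets = np.zeros(len(minutes))
    total_minutes = config.n_days * 1440.0
    n_events = rng.poisson(config.confounder_rate * config.n_days)
    spans = [
        ((iv.don - start_ts).total_seconds() / 60.0, (iv.doff - start_ts).total_seconds() / 60.0)
        for iv in intervals
    ]
    for _ in range(n_events):
        for _attempt in range(200):
            start = rng.uniform(0.0, max(total_minutes - config.confounder_duration, 1.0))
            end = start + config.confounder_duration
            if config.confounders_during_wear or not any(a < end and start < b for a, b in spans):
                lo = int(np.searchsorted(minutes, start, side="left"))
                hi = int(np.searchsorted(minutes, end, side="left"))
                offsets[lo:hi] += config.confounder_amp
                break
    return offsets


def simulate_temperature(
    schedule: list[WearInterval],
    config: SimConfig,
    participant_index: int = 0,
    pid: str | None = None,
) -> tuple[TemperatureSeries, SimTruth]:
    """Generate the sensor trace for one participant plus full ground truth.

    The state for the relaxation step ending at sample ``t_i`` is the wear
    mask at the start of the step, so a bout beginning exactly on a sample
    leaves that sample at the pre-don level and produces its first rise one
    sample later (sharp spike on donning, plateau near skin temperature,
    sharp fall on doffing).
    """
    schedule = sorted(schedule)
    for a, b in zip(schedule, schedule[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping wear intervals: {a} / {b}")
    pid = pid if pid is not None else participant_id(participant_index)
    rng = _rng(config, participant_index, _STREAM_TEMPERATURE)

    n = config.n_samples
    start_ts = pd.Timestamp(config.start_date)
    minutes = np.arange(n, dtype=float) * config.sampling_interval
    timestamps = start_ts + pd.to_timedelta(minutes, unit="m")

    mask = _wear_mask(schedule, start_ts, minutes)
    target_off = _ambient(config, minutes % 1440.0) + _confounder_offsets(
        config, rng, schedule, start_ts, minutes
    )

    k_on = float(np.exp(-config.sampling_interval / config.tau_on))
    k_off = float(np.exp(-config.sampling_interval / config.tau_off))
    t_skin = config.t_skin

    temps = np.empty(n)
    temps[0] = t_skin if mask[0] else target_off[0]
    prev = temps[0]
    for i in range(1, n):
        if mask[i - 1]:  # state held over the step that ends at sample i
            prev = t_skin + (prev - t_skin) * k_on
        else:
            a = target_off[i]
            prev = a + (prev - a) * k_off
        temps[i] = prev

    if config.sensor_noise_sd > 0:
        temps = temps + rng.normal(0.0, config.sensor_noise_sd, size=n)
    if config.quantization > 0:
        temps = np.round(np.round(temps / config.quantization) * config.quantization, 6)

    window = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    daily = daily_minutes(schedule, window, pid)
    series = TemperatureSeries(pid, pd.DatetimeIndex(timestamps), temps)
    truth = SimTruth(pid, schedule, daily, mask)
    return series, truth


def simulate_self_report(
    truth: SimTruth, config: SimConfig, participant_index: int = 0
) -> DailyWearSeries:
    """Biased day-level recall of the true wear minutes.

    True wear days are reported as ``round(max(0, gain_i * true + noise))``
    to the nearest ``report_rounding`` minutes; true no-wear days become
    phantom wear days with probability ``p_phantom_day``; entries go
    missing with the participant's missing-log rate (elevated for the
    hotspot participant when configured).
    """
    rng = _rng(config, participant_index, _STREAM_REPORT)
    gain_i = max(0.0, config.report_gain + config.report_gain_between_sd * rng.standard_normal())
    if config.p_missing_log_hotspot is not None and participant_index == config.hotspot_participant:
        p_missing = config.p_missing_log_hotspot
    else:
        p_missing = config.p_missing_log

    reported: dict[pd.Timestamp, float] = {}
    for date, true_min in truth.daily.minutes.items():
        if true_min > 0:
            value = round_to(config.report_rounding, max(0.0, gain_i * true_min + rng.normal(0.0, config.report_noise_sd)))
        elif rng.random() < config.p_phantom_day:
            phantom = _truncated_normal(
                rng, config.bout_minutes_mean, config.bout_minutes_sd, config.sampling_interval
            )
            value = round_to(config.report_rounding, phantom)
        else:
            value = 0.0
        if rng.random() < p_missing:
            value = np.nan  # entry absent from the log
        reported[date] = min(value, 1440.0) if np.isfinite(value) else value
    return DailyWearSeries(truth.participant_id, pd.Series(reported))


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate the full cohort: traces, self-report logs and ground truth."""
    cohort = Cohort()
    for i in range(config.n_participants):
        pid = participant_id(i)
        schedule = simulate_wear_schedule(config, i)
        series, truth = simulate_temperature(schedule, config, i, pid)
        log = simulate_self_report(truth, config, i)
        cohort.temperature[pid] = series
        cohort.selfreport[pid] = log
        cohort.truth[pid] = truth
    return cohort
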