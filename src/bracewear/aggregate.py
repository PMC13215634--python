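"""Daily attribution, rolling averages, and per-participant summaries.

Wear intervals are attributed to calendar days by overlap with
[00:00, 24:00) local, so a bout spanning midnight is split exactly.
Rolling windows are trailing, labelled by their last day, and are emitted
only where every day of the window is observed (non-missing) — a single
absent log entry suppresses every window that covers it.
"""

from __future__ import annotations

import pandas as pd

from .types import AggregateSummary, DailyWearSeries, InputError, WearInterval


def _window_index(window) -> pd.DatetimeIndex:
    if isinstance(window, pd.DatetimeIndex):
        return window.normalize()
    start, end = window
    return pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize(), freq="D")


def daily_minutes(
    intervals: list[WearInterval], window, participant_id: str = ""
) -> DailyWearSeries:
    """Sum interval overlap per calendar day; in-window days default to 0.

    Days with no wear are observed zeros, never missing: the sensor was
    recording, it just saw no bout.
    """
    index = _window_index(window)
    window_start = index[0]
    window_end = index[-1] + pd.Timedelta(days=1)
    minutes = pd.Series(0.0, index=index)
    for iv in sorted(intervals):
        if iv.don < window_start or iv.doff > window_end:
            raise InputError(f"interval {iv.don} -> {iv.doff} lies outside the window")
        day = iv.don.normalize()
        while day < iv.doff:
            day_end = day + pd.Timedelta(days=1)
            overlap = (min(iv.doff, day_end) - max(iv.don, day)).total_seconds() / 60.0
            minutes.loc[day] += overlap
            day = day_end
    return DailyWearSeries(participant_id, minutes)


def rolling_average(daily: DailyWearSeries, window_days: int) -> pd.Series:
    """Trailing mean over ``window_days``; complete, contiguous windows only."""
    if window_days < 1:
        raise InputError("window_days must be >= 1")
    rolled = daily.minutes.rolling(window=window_days, min_periods=window_days).mean()
    return rolled.dropna()


def summarize(daily: DailyWearSeries) -> AggregateSummary:
    """Totals over observed days: cumulative, average-daily, and days worn."""
    observed = daily.observed
    if observed.empty:
        raise InputError(f"all days missing for {daily.participant_id}")
    total = float(observed.sum())
    days_observed = int(len(observed))
    return AggregateSummary(
        participant_id=daily.participant_id,
        total_minutes=total,
        avg_daily_minutes=total / days_observed,
        days_worn=int((observed > 0).sum()),
        days_observed=days_observed,
    )
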