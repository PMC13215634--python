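"""Core domain containers shared across the pipeline.

All timestamps are naive local time (the study design is single-site).
A day runs over [00:00, 24:00) local; wear intervals are half-open
[don, doff) so that a sample falling exactly on a doff instant counts
as not worn and transitions are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(ValueError):
    """Statistically degenerate input (e.g. both vectors constant)."""


@dataclass(frozen=True, order=True)
class WearInterval:
    """One contiguous don -> doff wear bout, half-open [don, doff)."""

    don: pd.Timestamp
    doff: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.don < self.doff:
            raise InputError(f"WearInterval requires don < doff, got {self.don} >= {self.doff}")

    @property
    def duration_minutes(self) -> float:
        return (self.doff - self.don).total_seconds() / 60.0

    def overlaps(self, other: "WearInterval") -> bool:
        return self.don < other.doff and other.don < self.doff


@dataclass
class TemperatureSeries:
    """One participant's uniformly sampled sensor trace.

    ``timestamps`` must be strictly increasing.  Gaps (missing rows) are
    tolerated at construction; detection splits the series at any gap
    larger than twice the nominal sampling interval.
    """

    participant_id: str
    timestamps: pd.DatetimeIndex
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temps = np.asarray(self.temps, dtype=float)
        if len(self.timestamps) != len(self.temps):
            raise InputError("timestamps and temps must have equal length")
        if len(self.temps) < 2:
            raise InputError("TemperatureSeries needs at least 2 samples")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise InputError(f"timestamps for {self.participant_id} must be strictly increasing")
        if not np.all(np.isfinite(self.temps)):
            raise InputError(f"non-finite temperature for {self.participant_id}")

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def sampling_interval_minutes(self) -> float:
        """Nominal sampling interval (minutes), the modal inter-sample gap."""
        deltas = np.diff(self.timestamps.asi8) / (60 * 1_000_000_000)
        return float(np.median(deltas))

    def segments(self, max_gap_factor: float = 2.0) -> list[slice]:
        """Index slices of contiguous sampling, split at gaps > factor * interval."""
        interval = self.sampling_interval_minutes
        deltas = np.diff(self.timestamps.asi8) / (60 * 1_000_000_000)
        breaks = np.flatnonzero(deltas > max_gap_factor * interval)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks + 1, [len(self.temps)]])
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.timestamps,
                "temp_c": self.temps,
            }
        )


@dataclass
class DailyWearSeries:
    """Calendar-indexed daily wear minutes for one participant, one source.

    ``minutes`` is indexed by normalized dates; NaN marks a MISSING day
    (no log entry), which is distinct from an observed 0.
    """

    participant_id: str
    minutes: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.minutes, dtype=float)
        s.index = pd.DatetimeIndex(s.index).normalize()
        if s.index.has_duplicates:
            raise InputError(f"duplicate dates for {self.participant_id}")
        s = s.sort_index()
        vals = s.dropna()
        if ((vals < 0) | (vals > MINUTES_PER_DAY)).any():
            bad = vals[(vals < 0) | (vals > MINUTES_PER_DAY)]
            raise InputError(
                f"daily minutes outside [0, {MINUTES_PER_DAY}] for "
                f"{self.participant_id}: {bad.iloc[0]} on {bad.index[0].date()}"
            )
        self.minutes = s

    @property
    def observed(self) -> pd.Series:
        return self.minutes.dropna()

    @property
    def n_missing(self) -> int:
        return int(self.minutes.isna().sum())


@dataclass
class SimTruth:
    """Ground truth for one simulated participant."""

    participant_id: str
    intervals: list[WearInterval]
    daily: DailyWearSeries
    mask: np.ndarray  # bool, aligned to the TemperatureSeries samples


@dataclass
class AggregateSummary:
    """The aggregated outcome measures for one participant and source."""

    participant_id: str
    total_minutes: float
    avg_daily_minutes: float
    days_worn: int
    days_observed: int


@dataclass
class AgreementEstimate:
    """CCC + Bland-Altman limits of agreement at one aggregation level.

    ``bias`` and ``loa`` are on the self-report minus sensor orientation:
    over-reporting shows up as positive bias.
    """

    level: str
    ccc: float
    ccc_ci: tuple[float, float]
    bias: float
    loa: tuple[float, float]
    band: str
    n_pairs: int
    n_participants: int
    estimator: str
    ci_method: str
    orientation: str = "selfreport - sensor"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "ccc": self.ccc,
            "ccc_ci_lower": self.ccc_ci[0],
            "ccc_ci_upper": self.ccc_ci[1],
            "bias": self.bias,
            "loa_lower": self.loa[0],
            "loa_upper": self.loa[1],
            "band": self.band,
            "n_pairs": self.n_pairs,
            "n_participants": self.n_participants,
            "estimator": self.estimator,
            "ci_method": self.ci_method,
            "orientation": self.orientation,
        }


@dataclass
class Cohort:
    """Bundle of simulated per-participant traces, logs and ground truth."""

    temperature: dict[str, TemperatureSeries] = field(default_factory=dict)
    selfreport: dict[str, DailyWearSeries] = field(default_factory=dict)
    truth: dict[str, SimTruth] = field(default_factory=dict)

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.temperature)
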