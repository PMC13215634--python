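"""Validated configuration objects for simulation and detection."""

from __future__ import annotations

import datetime

from pydantic import BaseModel, Field, model_validator


class SimConfig(BaseModel):
    """Synthetic-cohort generator settings.

    Defaults emulate a 6-week knee-brace trial: temperature sampled every
    10 minutes at +/-0.1 degC precision, participants advised to wear the
    brace at least an hour a day, day-level self-report with noisy minute
    recall and over-reported wear days, and occasional missing log entries.
    """

    n_participants: int = Field(default=10, ge=1)
    n_days: int = Field(default=42, ge=1)
    sampling_interval: int = Field(default=10, ge=1, description="minutes between samples")
    start_date: datetime.date = datetime.date(2024, 1, 1)

    # thermal physics
    t_skin: float = 32.0
    t_ambient_mean: float = 22.0
    ambient_diurnal_amp: float = Field(default=2.0, ge=0)
    tau_on: float = Field(default=15.0, gt=0, description="warming time constant, minutes")
    tau_off: float = Field(default=20.0, gt=0, description="cooling time constant, minutes")
    sensor_noise_sd: float = Field(default=0.2, ge=0)
    quantization: float = Field(default=0.1, ge=0)

    # wear behaviour
    p_wear_day: float = Field(default=0.7, ge=0, le=1)
    bout_minutes_mean: float = Field(default=70.0, gt=0)
    bout_minutes_sd: float = Field(default=30.0, ge=0)
    allow_midnight_spanning: bool = False
    p_wear_day_between_sd: float = Field(default=0.15, ge=0)
    bout_mean_between_sd: float = Field(default=40.0, ge=0)

    # ambient confounders (hot car, air-conditioned room)
    confounder_rate: float = Field(default=0.1, ge=0, description="events per day")
    confounder_amp: float = 8.0
    confounder_duration: float = Field(default=40.0, gt=0, description="minutes")
    confounders_during_wear: bool = False

    # self-report bias model
    report_gain: float = Field(default=1.0, ge=0)
    report_gain_between_sd: float = Field(default=0.25, ge=0)
    report_noise_sd: float = Field(default=20.0, ge=0, description="minutes")
    report_rounding: int = Field(default=15, ge=1, description="minutes")
    p_phantom_day: float = Field(default=0.15, ge=0, le=1)
    p_missing_log: float = Field(default=0.05, ge=0, le=1)
    p_missing_log_hotspot: float | None = Field(default=None, ge=0, le=1)
    hotspot_participant: int = Field(default=0, ge=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if 1440 % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide 1440 minutes")
        if not self.t_skin > self.t_ambient_mean:
            raise ValueError("t_skin must exceed t_ambient_mean")
        return self

    @property
    def samples_per_day(self) -> int:
        return 1440 // self.sampling_interval

    @property
    def n_samples(self) -> int:
        return self.n_days * self.samples_per_day


def trial_config(seed: int = 0, **overrides) -> SimConfig:
    """Configuration mirroring the 6-week trial cohort.

    Ten participants, 42 days, and log missingness concentrated in one
    participant (expected ~13 of ~16 absent entries from the hotspot,
    matching the observed pattern of missing daily logs).
    """
    params = dict(
        n_participants=10,
        n_days=42,
        p_missing_log=0.008,
        p_missing_log_hotspot=0.31,
        hotspot_participant=0,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


class DetectConfig(BaseModel):
    """Gradient-based donning/doffing detector settings.

    The trigger is a run of up to ``confirm_samples`` consecutive same-sign
    differences whose cumulative change reaches the threshold; a noise-free
    donning step from ambient is ~4.9 degC per 10-minute sample, so the
    1.5 degC default clears quantized sensor noise (SD 0.2 degC) by a wide
    margin while remaining insensitive to diurnal ambient drift.

    The plateau check guards against the rare noise (or ambient-step)
    excursion that crosses the trigger: a donning event not followed by a
    sustained rise above the pre-don level within the first hour is
    cancelled rather than allowed to open an unbounded bout.
    """

    theta_on: float = Field(default=1.5, gt=0, description="degC rise triggering donning")
    theta_off: float = Field(default=1.5, gt=0, description="degC fall triggering doffing")
    confirm_samples: int = Field(default=2, ge=1)
    min_bout: float = Field(default=10.0, gt=0, description="minutes")
    merge_gap: float = Field(default=10.0, ge=0, description="minutes")
    plateau_check: bool = True
    plateau_rise: float = Field(default=3.0, gt=0, description="degC above pre-don level")
    plateau_samples: int = Field(default=2, ge=1)
    plateau_window: int = Field(default=6, ge=1, description="samples after donning inspected")
    gap_split_factor: float = Field(default=2.0, gt=0)
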