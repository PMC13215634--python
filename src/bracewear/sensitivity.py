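"""Sensitivity analyses for missing self-report handling.

Two scenarios beside the primary analysis: (1) missing log days imputed
as "no wear" (0 minutes) — imputation touches self-report only, since a
sensor day with zero detected wear is a measurement, not a missing value;
(2) exclusion of the participant who accounts for the most missing log
days (auto-identified, ties broken by participant id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .agreement import LEVELS, agreement_all_levels
from .types import AgreementEstimate, DailyWearSeries, InputError


def impute_no_wear(
    selfreport: dict[str, DailyWearSeries], window
) -> dict[str, DailyWearSeries]:
    """Replace every missing log day in the window with an observed 0."""
    if isinstance(window, pd.DatetimeIndex):
        index = window.normalize()
    else:
        start, end = window
        index = pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize(), freq="D")
    out = {}
    for pid, series in selfreport.items():
        filled = series.minutes.reindex(series.minutes.index.union(index)).copy()
        filled.loc[filled.index.isin(index) & filled.isna()] = 0.0
        out[pid] = DailyWearSeries(pid, filled)
    return out


def exclude_participants(
    sources: tuple[dict[str, DailyWearSeries], dict[str, DailyWearSeries]],
    ids: list[str],
) -> tuple[dict[str, DailyWearSeries], dict[str, DailyWearSeries]]:
    """Drop the given participants from both sources."""
    sensor, selfreport = sources
    unknown = set(ids) - set(sensor) - set(selfreport)
    if unknown:
        raise InputError(f"unknown participant ids: {sorted(unknown)}")
    sensor_out = {pid: s for pid, s in sensor.items() if pid not in ids}
    report_out = {pid: s for pid, s in selfreport.items() if pid not in ids}
    if len(set(sensor_out) & set(report_out)) < 2:
        raise InputError("fewer than 2 participants would remain after exclusion")
    return sensor_out, report_out


def most_missing_participant(selfreport: dict[str, DailyWearSeries]) -> str:
    """Participant with the most missing log days; ties -> lowest id."""
    counts = sorted(((s.n_missing, pid) for pid, s in selfreport.items()), key=lambda t: (-t[0], t[1]))
    return counts[0][1]


@dataclass
class SensitivityReport:
    scenarios: dict[str, dict[str, AgreementEstimate]]
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def deltas(self) -> dict[str, dict[str, dict[str, float]]]:
        """Per scenario and level: change in CCC and LoA bounds vs primary."""
        primary = self.scenarios["primary"]
        out: dict[str, dict[str, dict[str, float]]] = {}
        for name, ests in self.scenarios.items():
            if name == "primary":
                continue
            out[name] = {}
            for level, est in ests.items():
                base = primary[level]
                out[name][level] = {
                    "d_ccc": est.ccc - base.ccc,
                    "d_loa_lower": est.loa[0] - base.loa[0],
                    "d_loa_upper": est.loa[1] - base.loa[1],
                    "d_bias": est.bias - base.bias,
                }
        return out

    def to_dict(self) -> dict:
        return {
            "excluded_ids": self.excluded_ids,
            "scenarios": {
                name: {level: est.to_dict() for level, est in ests.items()}
                for name, ests in self.scenarios.items()
            },
            "deltas": self.deltas,
        }


def sensitivity_suite(
    sensor: dict[str, DailyWearSeries],
    selfreport: dict[str, DailyWearSeries],
    window=None,
    exclude_ids: list[str] | None = None,
    levels=LEVELS,
    **agreement_kwargs,
) -> SensitivityReport:
    """Primary + imputed-no-wear + exclusion scenarios across all levels."""
    if window is None:
        all_dates = pd.DatetimeIndex(
            sorted({d for s in selfreport.values() for d in s.minutes.index})
        )
        window = all_dates
    if exclude_ids is None:
        exclude_ids = [most_missing_participant(selfreport)]

    scenarios = {"primary": agreement_all_levels(sensor, selfreport, levels, **agreement_kwargs)}
    imputed = impute_no_wear(selfreport, window)
    scenarios["imputed_no_wear"] = agreement_all_levels(sensor, imputed, levels, **agreement_kwargs)
    sens_ex, rep_ex = exclude_participants((sensor, selfreport), exclude_ids)
    scenarios[f"excluded:{','.join(exclude_ids)}"] = agreement_all_levels(
        sens_ex, rep_ex, levels, **agreement_kwargs
    )
    return SensitivityReport(scenarios=scenarios, excluded_ids=exclude_ids)
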