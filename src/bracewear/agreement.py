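"""Agreement between sensor-measured and self-reported wear.

Two complementary views at every aggregation level:

* Lin's concordance correlation coefficient (CCC) — the moment estimator

      CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

  with population (divisor-n) moments, banded as <0.5 poor,
  0.5-0.75 moderate, 0.75-0.9 strong, >0.9 excellent.

* Bland-Altman 95% limits of agreement, mean difference +/- 1.96 SD
  (sample SD, divisor n-1), on self-report minus sensor so over-reporting
  shows as positive bias.

Repeated levels (daily, rolling) get a participant-level cluster
bootstrap CI — each resampled participant keeps all their days — so the
interval respects the repeated-measures structure; aggregated levels
(one pair per participant) use a Fisher z-transform interval.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .aggregate import rolling_average, summarize
from .types import AgreementEstimate, DailyWearSeries, DegenerateInputError, InputError

LEVELS = ("daily", "rolling3", "rolling7", "total", "avg_daily", "days_worn")
REPEATED_LEVELS = ("daily", "rolling3", "rolling7")
_BAND_ORDER = ("poor", "moderate", "strong", "excellent")


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-d vectors")
    if len(x) < 2:
        raise InputError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in agreement vectors")
    vx = x.var()  # divisor n
    vy = y.var()
    if vx == 0 and vy == 0:
        raise DegenerateInputError("both vectors constant; CCC undefined")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def band(ccc: float) -> str:
    """Qualitative agreement band for a CCC value."""
    if not -1.0 <= ccc <= 1.0:
        raise InputError(f"CCC out of range [-1, 1]: {ccc}")
    if ccc < 0.5:
        return "poor"
    if ccc <= 0.75:
        return "moderate"
    if ccc <= 0.9:
        return "strong"
    return "excellent"


def band_rank(label: str) -> int:
    return _BAND_ORDER.index(label)


def ccc_ci(ccc: float, n_effective: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform interval: tanh(atanh(ccc) +/- z / sqrt(n - 2))."""
    from scipy import stats

    if abs(ccc) >= 1.0:
        warnings.warn("CCC at the boundary; returning a point interval", stacklevel=2)
        return (float(ccc), float(ccc))
    if n_effective < 3:
        raise InputError("need n_effective >= 3 for a z-transform interval")
    z = 1.96 if confidence == 0.95 else stats.norm.ppf(0.5 + confidence / 2.0)
    half = z / np.sqrt(n_effective - 2)
    zc = np.arctanh(ccc)
    return (float(np.tanh(zc - half)), float(np.tanh(zc + half)))


def bland_altman_loa(diffs) -> tuple[float, float, float]:
    """(bias, lower, upper): mean difference +/- 1.96 * sample SD."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1 or len(diffs) < 2:
        raise InputError("need at least 2 differences")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return (bias, bias - 1.96 * sd, bias + 1.96 * sd)


def rm_corrected_sd(diffs, groups) -> float:
    """SD of differences corrected for multiple observations per individual.

    One-way ANOVA decomposition of the differences by participant: the
    between-subject variance component is recovered from the mean squares
    and added to the within-subject component, so subjects contributing
    many days do not drown out between-subject disagreement.
    """
    d = pd.Series(np.asarray(diffs, dtype=float))
    g = pd.Series(np.asarray(groups))
    counts = d.groupby(g.values).count()
    means = d.groupby(g.values).mean()
    k = len(counts)
    n = len(d)
    if k < 2:
        raise InputError("need >= 2 participants for the repeated-measures correction")
    if n == k:  # one observation per subject: nothing to correct
        return float(d.std(ddof=1))
    grand = d.mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((d - means.loc[g.values].to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    m0 = (n - float((counts**2).sum()) / n) / (k - 1)
    var_between = max((msb - msw) / m0, 0.0)
    return float(np.sqrt(var_between + msw))


def cluster_bootstrap_ci(
    panel: pd.DataFrame,
    statistic,
    n_boot: int = 2000,
    seed: int | None = None,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI resampling participants (clusters) with replacement.

    ``statistic(x, y)`` receives the pooled sensor/self-report vectors of
    one resample; each drawn participant contributes all of their rows.
    """
    pids = panel["participant_id"].unique()
    if len(pids) < 2:
        raise InputError("cluster bootstrap needs >= 2 participants")
    if n_boot < 200:
        raise InputError("n_boot must be >= 200")
    groups = {
        pid: (g["sensor"].to_numpy(float), g["selfreport"].to_numpy(float))
        for pid, g in panel.groupby("participant_id", sort=True)
    }
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        chosen = rng.choice(len(keys), size=len(keys), replace=True)
        xs = np.concatenate([groups[keys[i]][0] for i in chosen])
        ys = np.concatenate([groups[keys[i]][1] for i in chosen])
        try:
            stats_out[b] = statistic(xs, ys)
        except (DegenerateInputError, InputError, FloatingPointError):
            stats_out[b] = np.nan
            failures += 1
    if failures > 0.2 * n_boot:
        raise InputError(f"statistic undefined on {failures}/{n_boot} resamples")
    valid = stats_out[np.isfinite(stats_out)]
    alpha = (1.0 - confidence) / 2.0
    return (
        float(np.quantile(valid, alpha)),
        float(np.quantile(valid, 1.0 - alpha)),
    )


def vc_ccc(panel: pd.DataFrame) -> float:
    """Variance-components CCC via a subject random-intercept model.

    Stacks both methods' values, fits value ~ method with a random subject
    intercept (subject-by-method interaction folded into the residual) and
    returns sigma2_subject / (sigma2_subject + sigma2_resid + delta^2 / 2),
    where delta is the fixed method shift.
    """
    import statsmodels.api as sm

    long = pd.concat(
        [
            pd.DataFrame(
                {"value": panel["sensor"], "method": 0.0, "subject": panel["participant_id"]}
            ),
            pd.DataFrame(
                {"value": panel["selfreport"], "method": 1.0, "subject": panel["participant_id"]}
            ),
        ],
        ignore_index=True,
    )
    exog = sm.add_constant(long[["method"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(long["value"], exog, groups=long["subject"]).fit(reml=True)
    var_subj = float(fit.cov_re.iloc[0, 0])
    var_err = float(fit.scale)
    delta = float(fit.params["method"])
    return var_subj / (var_subj + var_err + delta**2 / 2.0)


def build_panel(
    sensor: dict[str, DailyWearSeries],
    selfreport: dict[str, DailyWearSeries],
    level: str,
) -> pd.DataFrame:
    """Aligned (participant, label, sensor, selfreport) rows for one level.

    Daily and rolling levels pair per-day values where both sources are
    observed; aggregated levels pair one summary per participant, each
    source summarized over its own observed days.
    """
    if level not in LEVELS:
        raise InputError(f"unknown level {level!r}; expected one of {LEVELS}")
    shared = sorted(set(sensor) & set(selfreport))
    if not shared:
        raise InputError("no participants present in both sources")
    rows = []
    excluded = []
    for pid in shared:
        s, r = sensor[pid], selfreport[pid]
        if level in REPEATED_LEVELS:
            if level == "daily":
                sv, rv = s.observed, r.observed
            else:
                w = 3 if level == "rolling3" else 7
                sv, rv = rolling_average(s, w), rolling_average(r, w)
            joined = pd.concat({"sensor": sv, "selfreport": rv}, axis=1, join="inner").dropna()
            if joined.empty:
                excluded.append(pid)
                continue
            for date, row in joined.iterrows():
                rows.append((pid, date, float(row["sensor"]), float(row["selfreport"])))
        else:
            try:
                ss, rs = summarize(s), summarize(r)
            except InputError:
                excluded.append(pid)
                continue
            field = {
                "total": "total_minutes",
                "avg_daily": "avg_daily_minutes",
                "days_worn": "days_worn",
            }[level]
            rows.append((pid, level, float(getattr(ss, field)), float(getattr(rs, field))))
    if not rows:
        raise InputError(f"empty overlap at level {level!r}; excluded participants: {excluded}")
    panel = pd.DataFrame(rows, columns=["participant_id", "label", "sensor", "selfreport"])
    panel.attrs["level"] = level
    panel.attrs["excluded"] = excluded
    return panel


def agreement_at_level(
    sensor: dict[str, DailyWearSeries],
    selfreport: dict[str, DailyWearSeries],
    level: str,
    n_boot: int = 2000,
    seed: int | None = None,
    compute_ci: bool = True,
    rm_loa_correction: bool = False,
    use_vc_ccc: bool = False,
) -> AgreementEstimate:
    """Full agreement estimate (CCC with CI, bias, LoA, band) at one level."""
    panel = build_panel(sensor, selfreport, level)
    x = panel["sensor"].to_numpy(float)
    y = panel["selfreport"].to_numpy(float)
    n_participants = panel["participant_id"].nunique()

    if use_vc_ccc and level in REPEATED_LEVELS:
        ccc = vc_ccc(panel)
        estimator = "variance-components (subject random intercept)"
    else:
        ccc = lin_ccc(x, y)
        estimator = "Lin moment (pooled pairs)"

    diffs = y - x
    if np.allclose(diffs, diffs[0]):
        bias = float(diffs.mean())
        loa = (bias, bias)
    elif rm_loa_correction and level in REPEATED_LEVELS:
        bias = float(diffs.mean())
        sd = rm_corrected_sd(diffs, panel["participant_id"])
        loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    else:
        bias, lo, hi = bland_altman_loa(diffs)
        loa = (lo, hi)

    if not compute_ci:
        ci = (float("nan"), float("nan"))
        ci_method = "none"
    elif level in REPEATED_LEVELS:
        if abs(ccc) >= 1.0 or n_participants < 2:
            ci = (ccc, ccc)
            ci_method = "degenerate point interval"
        else:
            ci = cluster_bootstrap_ci(panel, lin_ccc, n_boot=n_boot, seed=seed)
            ci_method = f"cluster bootstrap (participants, percentile, B={n_boot})"
    else:
        if abs(ccc) >= 1.0:
            ci = (ccc, ccc)
            ci_method = "degenerate point interval"
        elif n_participants < 3:
            ci = (float("nan"), float("nan"))
            ci_method = "unavailable (fewer than 3 participants)"
        else:
            ci = ccc_ci(ccc, n_participants)
            ci_method = "Fisher z (n = participants)"

    return AgreementEstimate(
        level=level,
        ccc=float(ccc),
        ccc_ci=ci,
        bias=float(bias),
        loa=loa,
        band=band(ccc),
        n_pairs=len(panel),
        n_participants=int(n_participants),
        estimator=estimator,
        ci_method=ci_method,
    )


def agreement_all_levels(
    sensor: dict[str, DailyWearSeries],
    selfreport: dict[str, DailyWearSeries],
    levels=LEVELS,
    **kwargs,
) -> dict[str, AgreementEstimate]:
    return {level: agreement_at_level(sensor, selfreport, level, **kwargs) for level in levels}
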