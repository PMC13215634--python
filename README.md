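# bracewear

Objective wear-time measurement for temperature-instrumented knee
braces, and agreement between sensor-measured and self-reported
adherence.

Clinical trials of wearable orthoses usually measure adherence with
daily self-report logs, which are prone to recall error and social
desirability bias. A small temperature sensor embedded in the brace
offers an objective alternative: skin contact drives the sensor toward
skin temperature, removal lets it relax back to ambient, so donning and
doffing appear as sharp spikes and drops in the trace. This package —
aimed at rehabilitation researchers and trialists — implements the full
analysis pipeline:

* **simulate** — synthetic cohorts (wear schedules, Newtonian-relaxation
  temperature traces sampled every 10 min at ±0.1 °C, biased daily
  self-report with phantom wear days and missing log entries) with full
  ground truth;
* **detect** — gradient-based donning/doffing detection: a spike is a
  run of ≤2 consecutive positive 10-min differences summing to ≥1.5 °C
  (drops analogously), paired into bouts by a state machine, with a
  plateau-confirmation guard; working on first differences makes the
  detector independent of ambient temperature level;
* **aggregate** — daily minutes, 3- and 7-day trailing rolling
  averages, cumulative minutes, average daily minutes, days worn;
* **agreement** — Lin's concordance correlation coefficient
  CCC = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²), banded (<0.5 poor, 0.5–0.75
  moderate, 0.75–0.9 strong, >0.9 excellent), and Bland–Altman 95%
  limits of agreement (mean difference ± 1.96 SD, self-report − sensor),
  with participant-level cluster-bootstrap CIs at repeated levels;
* **sensitivity** — missing logs imputed as no-wear, and exclusion of
  the highest-missingness participant.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate a trial-scale cohort (10 participants × 42 days), detect wear,
and quantify agreement at every aggregation level:

```python
import pandas as pd
from bracewear import trial_config, simulate_cohort, detect_wear
from bracewear import daily_minutes, agreement_all_levels

cfg = trial_config(seed=1)
cohort = simulate_cohort(cfg)
window = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
sensor = {pid: daily_minutes(detect_wear(s), window, pid)
          for pid, s in cohort.temperature.items()}
for level, est in agreement_all_levels(sensor, cohort.selfreport,
                                       n_boot=2000, seed=1).items():
    print(f"{level:10s} CCC {est.ccc:.2f} ({est.band}), "
          f"LoA {est.loa[0]:.0f} to {est.loa[1]:.0f}")
```

which prints:

```
daily      CCC 0.74 (moderate), LoA -59 to 56
rolling3   CCC 0.81 (strong), LoA -33 to 32
rolling7   CCC 0.84 (strong), LoA -22 to 22
total      CCC 0.82 (strong), LoA -965 to 611
avg_daily  CCC 0.94 (excellent), LoA -14 to 11
days_worn  CCC 0.66 (moderate), LoA -11 to 5
```

Daily self-report agrees only moderately with the sensor and the daily
limits of agreement are wide (±~1 h); rolling averages narrow them
roughly with the square root of the window; and the average daily wear
time over the whole period agrees excellently — day-to-day recall
errors wash out of long-term averages, while counts of days worn stay
unreliable. The same pipeline is available from the shell
(`bracewear simulate|detect|aggregate|agree|sensitivity|run`, each with
`--help`).

The numbered scripts under `analysis/` run this study end to end —
cohort generation, detection vs truth, aggregation, agreement,
sensitivity scenarios, and a Monte-Carlo detector validation — writing
their tables to `results/` (raw data goes to `scratch/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_detect_wear.py
...
python analysis/06_detection_validation.py
```

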