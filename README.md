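# circafeed

Circadian rhythms and diurnal patterns in the hourly feed intake of
individual growing-finishing pigs, from raw electronic-feeding-station
(EFS) visit records.

Feeding behaviour recorded by EFSs — single-space feeders with an RFID
antenna and a load cell — is a promising welfare and health indicator,
but individual animals vary enormously in *when* they eat within the day
and in how regularly that within-day pattern repeats. `circafeed`
separates and quantifies the two dimensions of that variation:

- **Circadian rhythm** — does the behaviour recur on a ~24 h cycle?
  Detected per animal per day with a Morlet continuous wavelet transform
  of the stationarised hourly intake series over periods 8–48 h, with
  pointwise significance against 1000 white-noise surrogates. A day
  counts as circadian when the median surrogate p-value over its 24
  hourly points in the 23.5–24.5 h period band falls below 0.05.
- **Diurnal pattern** — what does the within-day shape look like?
  Modelled per animal with a two-part (hurdle) generalised additive
  model: eating probability π(hour, day) by a logistic GAM and positive
  intake μ(hour, day) by a gamma GAM with log link, each combining a
  trend spline across days (4 knots) with a cyclic diurnal spline per
  14-day period (8 knots on the 24 h circle). Expected intake is π·μ.
  Eight features summarise each animal-period: number of peaks; timing,
  height and width of the highest peak; lowest intake; proportion of
  intake at night (21:00–05:00); and the minimum and maximum fitted
  eating probabilities (day-to-day consistency).

Consistency across the fattening phase is then quantified with a linear
mixed model per feature — period fixed, pen and pig random, AR(1)
residual correlation between an animal's consecutive periods — giving
pen and pig intraclass correlations, plus per-period Spearman matrices
relating all features to each other and to the proportion of circadian
days.

A fully seeded synthetic-cohort generator (hurdle draws from programmed
diurnal profiles with growth trend, day-to-day jitter, missing days and
injectable recording errors) provides ground truth for every stage, so
the whole pipeline is testable without any proprietary data.

## Worked example

```python
import numpy as np
from circafeed.synth import CohortSpec, alternans_profile, generate_hourly
from circafeed.detrend import prepare_series
from circafeed.wavelet import morlet_cwt, surrogate_pvalues, call_circadian_days
from circafeed.hurdle_gam import assign_periods, fit_hurdle
from circafeed.features import features_for_fit

spec = CohortSpec(n_days=28, missing_day_prob=0.0, seed=1)
pig = generate_hourly(alternans_profile(consistency=1.0), spec)

det = prepare_series(pig)                      # LOESS + amplitude + zero fill
sp = surrogate_pvalues(morlet_cwt(det), det, n_sim=300, seed=2)
calls = call_circadian_days(sp)
print(calls.loc[calls.evaluable, "is_circadian"].mean())

fit = fit_hurdle(pig, assign_periods(1, 28))
print(features_for_fit(fit).round(2).to_string(index=False))
```

prints

```
1.0
 pig_id  period_id  n_peaks  peak_time_h  peak_height  peak_width  lowest_intake  night_prop  min_prob_eat  max_prob_eat
pig0000          1      2.0         16.7       322.04       21.35           3.21        0.03          0.04          0.93
pig0000          2      2.0         16.8       529.76       41.20           2.52        0.02          0.03          0.96
```

The animal replays a strict alternans profile (small 09:00 peak, larger
16:30 peak), so every evaluable day is called circadian, both 14-day
periods recover the programmed two-peak shape with the main peak near
16:30, night intake is a few percent of the total, and the high maximum
/ low minimum eating probabilities reflect its perfect day-to-day
consistency. The peak grows between the periods because intake rises
with growth; the de-trended features remove the within-period trend,
not the between-period level.

The same pipeline runs end to end from the command line:

```bash
circafeed simulate --outdir demo --n-pens 2 --pigs-per-pen 4 --n-days 42
circafeed run-all --outdir demo_out --seed 7
```

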