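# aircco

Bayesian time-stratified case-crossover analysis of short-term air
pollution and pediatric asthma emergency-department (ED) visits — from
gridded exposure fields, through referent-window construction, to a
hierarchical Bernoulli-logit model and interquartile-range-scaled odds
ratios — with a synthetic-data generator so the whole pipeline is testable
against known effect sizes without any restricted health data.

It is aimed at environmental epidemiologists and biostatisticians who work
with case-only administrative health records and daily exposure surfaces.

## The design and the model

Each ED visit (case) is matched to up to three referent windows from the
same year, month and day of week; exposure for every window is a 3-day
moving average (3DMA) over lag days 0, 1, 2.  Case-crossover contrasts
control all time-invariant confounding; time stratification controls
day-of-week structure, seasonality and trend.  Seasons are *asthma seasons*
defined by relative ED burden (winter Jan 1–Feb 28/29, spring Mar 1–May 31,
summer Jun 1–Aug 19, fall Aug 20–Dec 31).

For visit *i*, window *j*:

```
y_ij ~ Bernoulli(pi_ij)
logit(pi_ij) = alpha + d_c + beta_p' X_ij + beta_w' W_ij

beta_k | tau_k ~ N(0, tau_k^-1),   tau_k ~ Gamma(2, 1)
alpha | tau_a  ~ N(0, tau_a^-1),   tau_a = 1/sd_alpha^2, sd_alpha ~ U(0, 4)
d_c | tau_d    ~ N(0, tau_d^-1),   tau_d ~ Gamma(2, 0.5)
```

with `X` the pollutant 3DMAs (NOx, O3, SO2, PM2.5, coarse PM10-2.5), `W`
temperature, dewpoint and their interaction, and `d_c` one random effect
per year-month-day-of-week stratum (840 over a 10-year study).  Fitting is
blockwise MCMC written in numpy: conjugate Gibbs steps for the precisions,
adaptive random-walk Metropolis for the location parameters, and a
vectorized per-stratum Metropolis sweep for the `d_c`.  Results are
reported as `OR_IQR = exp(beta * IQR)` with equal-tailed 95% credible
intervals.  See `docs/methods.md` for assumptions, defaults and known
limitations.

## Worked example

Simulate a two-year, 20-tract study with known effects — NOx at
0.0095 log-odds per ppb and coarse PM at 0.02 per ug/m3 — and fit the
overall model:

```python
import datetime as dt
from aircco import pipeline, report, synthetic_data

cfg = synthetic_data.SimConfig(
    n_tracts=20,
    start_date=dt.date(2005, 1, 1),
    end_date=dt.date(2006, 12, 31),
    true_betas={"NOx": 0.0095, "PM10-2.5": 0.02},
    target_daily_visits=4.0,
    seed=11,
)
result = pipeline.run_pipeline(
    cfg, scopes=("overall",), n_iter=3000, n_burnin=1000, n_chains=2
)
print(result.fits["overall"].removals)
print(report.format_or_table(result.or_table, units={"NOx": "ppb"}))
```

This simulates 2,906 visits (11,608 case/referent rows), and the
collinearity screen removes CO (|r| = 0.999 with NOx — the generator builds
them from a shared combustion driver) and dewpoint (|r| = 0.971 with
temperature), exactly the removals this model family makes on real data.
The fitted table begins:

```
Variable        overall
NOx             1.140*
                (1.059,1.221)
                9.761 ppb
```

read as: an interquartile-range (9.761 ppb) increase in the NOx 3DMA
multiplies the odds of an ED visit by 1.140 (95% CrI 1.059–1.221; the star
marks an interval excluding 1).  The simulated truth at that IQR is
`exp(0.0095 * 9.761) = 1.097`, inside the interval.  A command-line
interface wraps the same flow: `aircco simulate`, `aircco run`,
`aircco fit --season fall`.

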