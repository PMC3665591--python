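# wheatear-stopover

Analysis tools for the stopover ecology of Arctic nocturnal songbird
migrants: when do birds leave a stopover site, in which direction, at what
time of night, and with how much fuel?

The package grew out of a classic field problem: juvenile northern wheatears
(*Oenanthe oenanthe*) staging at the Bering Strait before a ~15,000 km
migration to East Africa. It bundles everything that analysis chain needs —
fuel-load energetics, solar and wind geometry, compass-course predictions,
circular statistics of nocturnal departures, a covariate-constrained
state-space Cormack-Jolly-Seber (CJS) model with two-step informative
priors, Monte Carlo stopover-duration estimation, and a synthetic-study
generator so the whole pipeline can be exercised and validated end to end
without any field data.

## The models in brief

**Energetics.** Fuel load is `f = (m − m_lean)/m_lean` with lean mass
predicted from wing length (`0.29 g/mm · wing − 6.85 g`). A fuel load buys a
potential flight duration `T(f) = 100 ln(1 + f)` hours; the realized
nocturnal range is `airspeed · min(T(f), time to sunrise)` plus tailwind
displacement. The time-minimizing departure fuel load solves the
marginal-value condition `T′(f*) = T(f*)/(f* + k·τ)` for deposition rate `k`
and settling time `τ`.

**Departure model.** Presence at the site is a latent absorbing state:
`z[i,t] ~ Bern(z[i,t−1] Φ[i,t−1])`, detection `Y[i,t] ~ Bern(z[i,t] p[i,t])`,
conditioning on first capture. Staging probability Φ (1 − nightly departure
probability) is logit-linear in day-since-arrival, centered study day,
standardized weather (temperature, surface wind, tailwind component), a
transient indicator, and either standardized arrival fuel load or raw
evening fuel load; detection p is logit-linear in a radio-tag indicator and
surface wind. The likelihood marginalizes `z` exactly with a two-state
forward recursion; posteriors come from an ensemble MCMC sampler. A two-step
fit passes step-1 posteriors (birds without evening fuel loads) forward as
moment-matched normal priors on the shared coefficients of the
evening-fuel-load model.

**Stopover duration.** For each bird, nightly departure probabilities
predicted after its last observation (over posterior draws, with covariates
extended by an explicit rule) are simulated forward to the departure night;
durations include the arrival day.

**Circular statistics.** Vector mean and mean resultant length R, the
Rayleigh uniformity test with finite-sample correction, dispersion-based and
bootstrap confidence intervals for the mean direction, and circular-linear
correlation with a randomization p-value.

## Worked example

The packaged radio-tracking table (30 birds, autumn 2010) analysed in one
call:

```python
from wheatear_stopover.pipeline import run_departure_analysis
from wheatear_stopover.synthdata import table1_fixture

report = run_departure_analysis(table1_fixture(), declination=11.19, seed=0)
print(report["direction"])
print(report["minutes_after_sunset"])
```

prints (abridged):

```
{'n': 15, 'mean_direction': 232.87, 'R': 0.8725,
 'ci95': [216.7, 249.0], 'rayleigh_p': 5.6e-07}
{'n': 16, 'mean': 85.1, 'sd': 28.8, 'range': [29.0, 128.0]}
```

Fifteen departure directions cluster tightly around 233° (R = 0.87, Rayleigh
p < 10⁻⁴): the birds headed south-west, matching a constant
geographic/magnetic course (243°/232° from standard geodesy) rather than the
337° great-circle route. Sixteen departures averaged 85 ± 29 min after
sunset — take-off in twilight, leaving most of the night for flight.

The `examples/` directory holds one short script per capability
(departure analysis, flight range, compass courses, simulate-and-fit,
stopover durations), and a thin CLI wraps the same functions:

```sh
wheatear-stopover courses --origin 65.6167,-168.0833 --dest 8,34 --declination 11.19
wheatear-stopover simulate --seed 1 --out study/
wheatear-stopover run-all --out results/ --seed 1
```

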