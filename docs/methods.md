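# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Fuel-load energetics

Fuel load is the dimensionless fuel fraction `f = (m − m_lean)/m_lean`.
Lean mass comes from the wing-length allometry `0.29 g/mm · wing − 6.85 g`
established for this species; wing lengths at or below 23.62 mm are rejected
(non-positive lean mass). For radio-tagged birds the transmitter-plus-harness
mass (default 0.8 g) is subtracted from every weighing before the fuel
fraction is formed.

The evening body mass of a day is the last balance weighing within two hours
before that day's sunset. Because the study site sits at ~168° W, the UTC
calendar date of an evening weighing usually differs from the study day;
weighings are therefore matched to study days by the pre-sunset time window,
not by calendar date. The evening fuel load of the last stopover day is the
departure fuel load (no extrapolation), and the total fuel deposition rate is
`(departure fuel load − arrival fuel load)/minimum stopover duration`. The
printed form of this rate equation is ambiguous about parenthesization; the
implementation uses the fuel-load difference because only that reading
reproduces the published 0.04 day⁻¹ from the published means (0.42, 0.25,
4.5 d).

Potential flight duration is `T(f) = 100 ln(1+f)` hours (strictly
increasing, concave, exactly inverted by `exp(T/100) − 1`). Nocturnal range
takes `min(T(f), minutes to sunrise/60)` hours of flight at a configurable
airspeed and adds tailwind displacement over the flight duration. The
default airspeed, 46.8 km/h (13 m/s), is back-derived from the published
duration/distance pairs (22.31 h ↔ 1050 km, 35.07 h ↔ 1637 km); "restricted
flight range" is implemented as airspeed × that time-or-fuel-limited
duration, the only reading consistent with the stated inputs.

The time-minimizer reference curve solves the marginal-value condition
`T′(f*) = T(f*)/(f* + k·τ)`, equivalently `(1+f*) ln(1+f*) − f* = k·τ`, by
bracketed Brent root-finding on (0, 10] to |residual| < 1e−9. `f*` is 0 at
`k·τ = 0` and increases with it. The "local variation" variant of this curve
is not implemented (its formulation is not reconstructible from the
available description).

## Solar geometry and wind support

Sun elevation, sunset and sunrise use the standard NOAA solar-position
equations (truncated Meeus ephemeris: geometric mean longitude/anomaly,
equation of center, apparent longitude, corrected obliquity, declination,
equation of time), accurate to a few hundredths of a degree over 1950–2050.
Sunset and sunrise are defined at geometric elevation −0.833° (the NOAA
convention), found by a three-step fixed-point iteration on the hour angle;
polar day/night raise an explicit error. `sun_elevation` applies the NOAA
refraction correction by default; `refraction=False` returns the geometric
elevation, which equals −0.833° exactly at the computed event instants.
Internal consistency with the study's printed values: night length on the
first/last study nights computes to 411/554 min (printed 410/554), and every
printed (minutes-after-sunset, sun-elevation) departure pair is reproduced
within 0.5°.

The tailwind component is `cos(direction_to − goal) × speed` with wind
direction in the "blowing toward" convention (add 180° to convert from the
meteorological "from" convention). When several pressure levels are
available (surface, 1000, 925, 850, 700 mbar) the level maximum is used,
since nocturnal migrants select flight altitude. The daily covariate table
expects one midnight value per day (`twc_midnight_ms`), either precomputed
or derived from the per-level columns; interpolation of 6-hourly reanalysis
to local midnight is the user's responsibility. The detection model uses
same-day surface wind (one published table labels this covariate with a
t+1 subscript while the text describes a same-day effect; same-day is
implemented).

## Compass courses

All course computations use a sphere; predictions are quoted to whole
degrees and the ellipsoidal correction is far below that. Longitude
differences are normalized to (−180°, 180°] first (the shortest path from
the Bering Strait to Africa runs west). Great-circle initial bearing uses
the standard atan2 formula; the rhumb line uses the Mercator-latitude
difference. Magnetic and geographic frames convert by the scalar declination
(east positive): geographic = magnetic + declination. No geomagnetic field
model is included.

On the published endpoints (65°37′ N 168°5′ W → 8° N 34° E) standard
geodesy gives 337.4° (orthodrome) and 243.2° (loxodrome), not the 336° and
251° sometimes quoted for this route; the source of that difference is not
documented, so the implementation follows standard formulas and is validated
by geodesy identities (equator/meridian agreement, round-trip declination,
and numerical integration of the constant-bearing path reaching the
destination meridian within 0.5°).

## Circular statistics

Angles are degrees at the interface, radians internally. The mean direction
and mean resultant length R come from the component means; the mean is
flagged undefined when R = 0. The Rayleigh p-value uses the
Zar/Greenwood–Durand finite-sample approximation
`p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n))`, accurate at the 10⁻⁴ level
for n in the teens (checked against a 100,000-draw Monte Carlo null).

The confidence interval for the mean direction is the large-sample
dispersion interval (circular standard error
`σ² = (1 − ρ₂)/(2nR²)` with `ρ₂` the mean of `cos 2(θ − μ̂)`; interval
`μ̂ ± asin(z σ)`), with a bootstrap fallback that engages automatically when
the dispersion formula breaks down (asin argument ≥ 1) and is also available
on request. Both are exposed because the interval construction used for the
published 218°–249° interval is not specified; the dispersion interval
reproduces it to within ~1.5° per bound.

The circular-linear correlation is
`r² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs)/(1 − r_cs²)`; its p-value is a
randomization test permuting x against the angles, counting permutations
with r at least the observed value and estimating p as
`(count + 1)/(n_perm + 1)`. The seed is an explicit argument; with many
permutations the estimate matches exhaustive enumeration on small samples
within 0.01.

## The state-space CJS model

Staging probability Φ (probability of surviving and staying one more day;
daily survival is ≈ 1 at this time scale, so 1 − Φ is the departure
probability) and detection probability p are logit-linear:

* detection: intercept, radio-tag indicator, standardized surface wind;
* staging, arrival-fuel-load form: intercept, day since arrival (`daysa`,
  1 on the arrival day), centered study day (`day.c`, spanning −10..10 for a
  21-day season), standardized arrival fuel load, standardized temperature,
  wind, and tailwind component, an arrival-day transient indicator
  (`indfirst`), and the arrival-fuel-load × day interaction;
* staging, evening-fuel-load form: the same with raw evening fuel load (and
  its day interaction) replacing arrival fuel load. Evening fuel load enters
  unstandardized by design, so its coefficient reads per unit of fuel load.

Weather covariates are standardized over study days, arrival fuel load over
individuals; zero-variance columns standardize to zero with a warning.
Transients are handled through the `indfirst` coefficient, not a separate
mixture class.

**Likelihood.** Rather than sampling the latent presence states, the
likelihood marginalizes them with a forward recursion over the two states
{present, departed}; departed is absorbing with detection probability zero.
This is exact (it agrees with brute-force enumeration over all departure
days to 10⁻¹⁰) and makes the posterior sampler-agnostic; it is equivalent by
construction to the data-augmented formulation used in BUGS-style software.

**Priors and sampling.** All logit-scale coefficients get independent
Normal(0, sd 31.62) priors by default (precision 0.001, the conventional
vague prior in the BUGS ecosystem; the very wide published interval for the
radio-tag detection coefficient — 97.5% quantile ≈ 72 — is only consistent
with a prior of about this width, since the likelihood is flat on that
direction above ~5). Posteriors are drawn with the affine-invariant ensemble
sampler (emcee), using differential-evolution moves (80% DE, 20% DE-snooker),
which mix far better than stretch moves on this posterior's flat radio-tag
direction. Walkers (minimum 26) start in a small ball around the posterior
mode found by direct optimization. Defaults: 40 walkers × 2,000 steps with
half discarded; Gelman–Rubin Rhat (walkers treated as chains) and effective
sample size are reported per coefficient, with a strict convergence flag at
Rhat 1.02 and a warning rather than silence on failure. The summary mirrors
the usual coefficient table: posterior mean, central 95% interval, Rhat,
n_eff, plus the deviance.

**Two-step informative priors.** Step 1 fits the arrival-fuel-load model to
the birds without evening fuel loads. Its posterior means and SDs become
moment-matched normal priors on the six staging coefficients shared with the
evening-fuel-load model (`daysa`, `day.c`, `temp.z`, `wind.z`, `twc.z`,
`indfirst`); the evening-fuel-load terms keep vague priors. Step 2 then fits
the evening-fuel-load subset, so the shared terms are informed by all birds.
Moment matching is used because "posterior as prior" does not itself fix a
distributional form. Step 2 is aborted only on gross step-1 non-convergence
(max Rhat > 1.1 by default, configurable); the strict 1.02 flag still warns.
On a synthetic split, the informative priors demonstrably narrow the shared
coefficients' intervals relative to fitting the evening-fuel-load subset
alone.

**Missing evening fuel loads** are imputed by a linear mixed regression of
evening fuel load on day since arrival with a per-bird random intercept
(REML via statsmodels MixedLM), falling back to a fixed-effects estimator
(per-bird intercepts, common slope) when too few birds have repeated
measures for the mixed fit. Observed values are never overwritten; birds
with no observations are excluded with a warning. Imputation is plug-in:
its uncertainty is not propagated, matching the original point-imputation
design.

## Stopover-duration Monte Carlo

The minimum stopover is last-detection day − first-capture day + 1 (gaps
tolerated). For the model-based duration, each simulation replicate takes a
posterior coefficient draw, carries the bird forward from its last
observation, and departs it after day t with probability 1 − Φ(t); the
duration counts calendar days from arrival through the day whose night the
bird leaves. Covariates beyond the study window follow an explicit,
configurable rule: weather columns carry their last observed value, the
centered study day continues linearly, and evening fuel load follows the
imputation model's per-bird trajectory capped at 1.3 (the most extreme fuel
load on record for the species). The horizon is 30 days after arrival;
with departure probability near 1 within two weeks the truncated mass is
negligible, and truncated draws are counted and warned about. Under a
constant Φ the extra days beyond the last observation are exactly
Geometric(1 − Φ), which the simulation reproduces (chi-square
goodness-of-fit at 10⁵ draws).

Two population standard errors are reported, because field studies are
inconsistent about which they quote: the posterior SD of the across-bird
mean (computed per replicate) and the across-bird SD of per-bird means over
√n.

## Synthetic-data generator

The generator emulates the study conditions: 105 birds over a 21-day season
starting 11 August 2010 at 65°37′ N 168°5′ W; staggered arrivals (uniform
over the season); wing lengths ~ N(95, 2) mm truncated to [85, 105] (the
species' plausible range — this only scales lean mass); arrival fuel loads
~ N(0.21, 0.09) truncated positive; per-bird fuel deposition rates
~ N(0.04, 0.02)/day with N(0, 0.02) day-to-day noise, capped at 1.3;
staging and detection driven by the published coefficient means as the
default truth (intercept 4.5, daysa −0.474, day.c −0.108, temp.z 0.787,
wind.z −0.118, twc.z 0.236, indfirst −0.830, efl −3.915, efl × day.c 0.328;
detection 2.946/30.796/−0.143); 30/105 birds radio-tagged (near-certain
detection) and 30/105 on the balances with evening masses observed on 85% of
present days; departure times ~ N(85, 29) min after sunset truncated to the
night; directions von Mises around 233° with concentration solved from
R = 0.87 via the Bessel-function ratio. Weather is an AR(1) temperature
series (mean 6 °C, sd 2.5, lag coefficient 0.6 — an ordinary Arctic-coast
August) and gamma-distributed wind speeds increasing with altitude with
uniform directions. One master seed spawns independent sub-streams per
output table, so any single table regenerates stably.

What the generator does **not** emulate: spatially realistic weather or
reanalysis structure, within-day mass dynamics (each day collapses to one
evening mass), individual heterogeneity in departure-time or direction
beyond the global distributions, observation of arrival *condition*
covariates (fat/muscle scores), or any movement after departure. Passing
recovery tests on these data therefore demonstrates that the estimator is
correct and calibrated under the model's own assumptions at realistic sizes
and effect strengths — not that the model is a complete description of real
field seasons.

**Parameter recovery.** Simulating 300-bird, 60-day seasons from the default
truth and fitting the evening-fuel-load model (32 walkers × 2,500 steps)
recovers the generating coefficients; across replicate seasons each
coefficient's 95% interval covers its true value at the nominal rate. With
twelve coefficients checked jointly over eight replicates, an occasional
6/8 coverage count for a single coefficient is the expected behaviour of a
calibrated estimator (the probability that at least one of twelve
coefficients misses twice in eight replicates is near one half even at
exactly 95% coverage); a 24-season calibration run showed no systematic bias
for any coefficient. The problem sizes here (300 × 60, eight replicates,
2,500 steps) were chosen to make the recovery experiment decisive while
staying at desk scale.

## The packaged tracking table

The 30-bird radio-tracking table ships verbatim: capture dates, departure
nights, departure times in minutes after local sunset, sun elevations at
take-off, and departure directions, with the tracking notes for birds that
were lost or transient. Sixteen rows carry a departure time, fifteen of
those a direction. The directions are stored as printed; whether those
printed values are compass (magnetic) or geographic bearings is ambiguous in
the source (the published direction *range* equals the table's raw range
shifted by the +11.19° declination, while the published mean and R are
reproduced by the raw values), so the departure analysis reports the raw
summary and, when a declination is supplied, the shifted summary alongside.

## Known limitations

* The two published course predictions (336°/251°) are not reproduced by
  standard geodesy on the published endpoints; the package documents the
  discrepancy rather than matching the numbers.
* Imputation uncertainty for missing evening fuel loads is not propagated.
* Rhat over ensemble walkers understates between-chain disagreement relative
  to independent chains; the strict 1.02 flag partially compensates, and
  n_eff is reported so users can judge.
* The published per-individual arrival-condition pairing (mean fuel load
  0.21 ↔ 18.4 h) reflects per-individual averaging of a concave function and
  cannot be checked without the individual table, which was not deposited;
  the package does not use it as a reference value.
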