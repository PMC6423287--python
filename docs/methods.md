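# Methods

`lapwing` turns second-resolution nest arrival/departure logs from
continuously monitored shorebird nests into the standard descriptors of a
biparental incubation rhythm, and ships a calibrated simulator so that every
estimator in the package can be validated against known ground truth without
field data.

## Definitions and segmentation

An **incubation bout** of one parent runs from its arrival at the nest to its
last departure before the partner takes over; the parent's own off-nest
excursions inside that span are **recesses**, and a bout has no maximum recess
length (single female bouts can approach two days). The interval from one
parent's final departure to the partner's arrival is an **exchange gap**,
attributed to the arriving parent. **Nest attendance** is the proportion of
monitored time a parent is physically on the nest (recesses excluded);
**responsibility** is the proportion covered by a parent's whole bouts,
recesses included.

Segmentation operates on half-open intervals `[start, end)` with integer
seconds, so every decomposition identity holds exactly:

```
attended_f + attended_m + recess_f + recess_m + gaps + unattributed = monitored
```

Conventions for awkward cases:

* a monitoring window that begins while a parent sits (first event is a
  departure) opens with that parent on the nest; the bout is flagged
  incomplete, as is any bout cut by a window edge — a bout is *complete*
  only when both boundaries are observed partner exchanges;
* a departure and partner arrival in the same second yield a recorded
  0-second gap, excluded from gap-length analyses (log scale);
* gaps cut by a monitoring break have unknown true length and are excluded
  from gap statistics;
* events flagged uncertain or observer-disturbed taint their bout; tainted
  bouts and their adjacent gaps are excluded, and the excluded time is
  subtracted from observed-time denominators.

The segmentation is verified, case by case and in bulk, against a brute-force
per-second state walk over the raw events (an independent code path), with
exact equality required.

## Solar geometry

Night is defined as the Sun more than 6° below the horizon (end of civil
twilight); sunrise and sunset use −0.833°. Elevation comes from the NOAA
low-precision solar-position series (day-angle Fourier expansion of equation
of time and declination), accurate to ≈0.1–0.2°, which moves a twilight
crossing by well under a minute at mid-latitudes. Crossings are located by a
60-s scan plus bisection to 1 s. A night is keyed to the civil date of the
evening it begins. Geometric elevation is used for the −6° rule (no
refraction correction); polar day/night return empty results rather than
errors.

## Aggregation filters

The inclusion rules mirror a typical field protocol and default to: hourly
rows need a fully monitored clock hour (3600 s, no excluded time) and a nest
with ≥24 such hours; daily rows need >90% of the calendar day monitored;
nest-level summaries need ≥2 included days. Bouts are split at hour/day
boundaries for time budgets but kept whole for bout-length analyses; per-sex
bout medians use complete, untainted bouts only (truncated bouts bias
medians downward). The longest female night bout per night considers female
bouts with ≥60% of their length in night and reports the maximum; nights
with no qualifying bout are omitted.

## Statistical models

Rhythmicity enters linear models through sine/cosine pairs of time in
radians, `rad = 2·t·π/p` for periods p = 12 and 24 h. Continuous predictors
other than time are z-transformed; per-nest and per-day responses are
weighted by the square root of monitored time. Mixed models are fitted by
REML (statsmodels `MixedLM`); when a random structure fails to converge the
fit steps down a fixed ladder — drop random slopes, then secondary variance
components, finally all random terms — and records the structure used.
Inference is by posterior simulation: 5000 draws from a multivariate normal
centred at the estimates with the coefficient covariance, summarised as
2.5/50/97.5 percentiles. No mixed-model p-values and no multiple-testing
correction are computed.

Because hourly female and male attendance are strongly inversely correlated,
the hourly rhythm model first samples one sex per nest-hour uniformly at
random (seeded), then fits sex × (sin12+cos12) + sex × (sin24+cos24) with
parent-within-nest grouping and a day-in-season variance component.

**Repeatability** (ICC) of daily attendance is `R = σ²_nest/(σ²_nest+σ²_res)`
from a gaussian random-intercept REML fit. The implementation profiles the
residual variance and grand mean out of the REML criterion, leaving a 1-D
search over the variance ratio — O(#nests) per evaluation — which makes the
5000-draw parametric bootstrap (simulate from the fitted model, refit,
percentile CI) run in seconds. It is cross-checked against statsmodels
MixedLM in the tests. Male repeatability excludes uniparental nests: their
identically-zero male attendance would contribute spurious between-nest
variance.

**Compensation** is defined as c = −(slope of female attendance on male
attendance, WLS weighted by √days): c = 1 means the female fully replaces
missing male incubation, c = 0 none. On noiseless linear tables the estimate
is exact to numerical precision; its CI comes from the same
posterior-simulation machinery.

## The simulator

`synthetic.simulate_study` draws an alternating-renewal event stream per
nest. Defaults are the study-like conditions: site 49.25° N 14.08° E
(UTC+2), April–June season, 27-day incubation period, 2–7 monitored days per
nest, 8% uniparental nests, male share ~ Beta(1.6, 2.8) scaled to [0, 0.4]
(population median ≈ 0.126 including uniparental zeros), overall attendance
targets centred so the population median is 0.87, per-sitting lognormal
durations with medians 60 min (female) / 32 min (male) and shape 0.7,
exchange gaps lognormal with median 1.9 min (minimum 6 s), whole-night
female incubation (p_night = 1) below the −6° threshold, and male take-over
weights bumped after sunrise and before sunset.

The female attendance target is coupled to the male share through the
configurable compensation slope, `f = f₀ − c·m + ε` with c = 0.62 by
default; overall attendance is `a = f + m`. Nest-level spread (sd 0.045)
plus the coupling reproduce the observed 0.68–0.94 attendance range as a
distributional consequence; a hard clip at those values is deliberately not
applied because it would bend the linear coupling that the
compensation-recovery tests rest on (targets are only clamped at wide
feasibility bounds, 0.60–0.97).

Realization is engineered so targets are met rather than merely expected:

* a trial renewal pass measures how the male take-over probability maps to
  realized daytime share (bout merging and night truncation distort the
  renewal-theory odds) and corrects it; within the final pass a proportional
  controller nudges the take-over rate toward the target share;
* male sitting time is deliberately overshot by ~15% and trimmed back to the
  nest's male-attendance target by male recesses; the female is trimmed to
  her own target f = a − m. Trimming each sex to its *own* target keeps the
  other sex's realization noise out of the coupling;
* recess budgets are settled at the nest level first (a deficit day borrows
  from surplus days) and then spread over days following per-day targets
  whose jitter (sd 0.05 attendance, 0.03 male) is symmetrically clipped and
  re-centred — both choices remove small ceiling-correlated biases;
* recesses are placed as disjoint intervals strictly inside daytime bout
  portions (≥1 s margins; nights stay recess-free), with at most 70% of a
  portion removable — a nest holding the whole night at 68% overall
  attendance must spend roughly half the daylight off the nest, so the cap
  has to clear that;
* at night-fall the sitter hands over and the female takes one bout spanning
  the night; the male relieves her right after dawn, which both matches the
  post-sunrise male peak and keeps whole-night bouts from merging with
  morning bouts.

Every bundle passes validation with zero fatal errors by construction, and
per-nest seeds are spawned from the master seed via `numpy.random
.SeedSequence`, so identical configurations reproduce byte-identical files.

What the simulator does *not* emulate: weather- and predator-driven recess
clustering, true nest failure and abandonment, observer mis-sexing,
egg-temperature dynamics, and temporal autocorrelation of bout lengths
beyond the previous-bout term. Passing recovery tests therefore demonstrates
estimator correctness under the stated generative structure, not robustness
to every failure mode of field data.

Two direct table generators bypass the event level for estimator
calibration: `simulate_daily_attendance` (gaussian random-intercept daily
attendance with exact variance components, used for ICC recovery at R = 0,
0.54, 0.70) and `simulate_hourly_rhythm` (injected 24-h cosine rhythm with
known amplitude and peak hour).

## Known limitations

* Pooled bout medians from the simulator (~170 min female, ~42 min male at
  default settings) exceed the configured per-sitting medians, because
  consecutive same-sex sittings merge into one bout whenever the partner
  does not take over — at a 13% male share, most female sittings are not
  followed by male incubation. This is a property of the bout definition,
  not a bug; forcing pooled medians down per nest would erase the
  between-nest bout-length variation the median-bout model needs.
* With zero compensation configured, overall attendance grows one-for-one
  with male share, so recovery tests for c = 0 use a lower attendance centre
  (0.72) and male-share ceiling (0.2) to keep targets inside the ~96%
  physical coverage limit.
* `MixedLM` supports one grouping factor; genuinely crossed random
  intercepts are approximated through variance components, with the fallback
  ladder as a safety net.
* The solar module ignores refraction variation with pressure/temperature
  and treats the −6° rule geometrically.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script work at study scale chosen for
desk-top reproducibility: 60 nests × 3 days for pipeline summaries,
compensation and ICC recovery; 30 nests × 3 days of hourly data for rhythm
recovery; 1000 randomized streams for the segmentation oracle; bootstrap
sizes 500 (coverage study, 50 replicates) and 5000 (reported CIs).
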