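# lapwing

Incubation-rhythm analysis for biparentally incubating shorebirds.

Continuous video or logger monitoring of a nest yields a stream of
time-stamped arrival and departure events of the two parents. This package
turns such event logs into the standard descriptors of an incubation
rhythm — incubation bouts, exchange gaps, recesses, and nest attendance at
hourly, daily and whole-nest scales — and fits the statistical models a
behavioural ecologist asks of them: circadian harmonic regressions,
repeatability (ICC) of daily attendance, and the degree to which the female
compensates for a low-contributing male. A calibrated synthetic-study
generator makes the whole pipeline testable end to end with known ground
truth.

It is written for behavioural ecologists and chronobiologists working with
nest-attendance biologging data, in particular from species with highly
variable male contributions (lapwings, plovers and other shorebirds).

## The quantities at the core

For a parent *p* with bouts *B_p* (each bout running from arrival to the
last departure before the partner's take-over, recesses included) over
monitored time *T*:

* attendance `A_p = (Σ_{b∈B_p} |b| − recesses) / T`, responsibility
  `R_p = Σ_{b∈B_p} |b| / T`;
* circadian structure is modelled with harmonic terms
  `rad_P(t) = 2πt/P`, fitting `sin(rad_P)` and `cos(rad_P)` for P = 12, 24 h
  in REML mixed models, with 95% credible intervals from 5000 posterior
  draws of the coefficients;
* repeatability of daily attendance `R = σ²_nest / (σ²_nest + σ²_res)` from
  a random-intercept REML fit, CI by parametric bootstrap;
* compensation `c = −slope` of the female-on-male attendance regression
  (WLS, weights √days): c = 1 full compensation, c = 0 none;
* night is the Sun more than 6° below the horizon (NOAA solar-position
  algorithm); sunrise/sunset use −0.833°.

## Worked example

Simulate a 10-nest study, analyze it, and print the headline estimates:

```sh
lapwing simulate --n-nests 10 --seed 42 --out sim
lapwing analyze --events sim/events.csv --windows sim/windows.csv \
                --metadata sim/metadata.csv --seed 42 --out run
lapwing report run
```

which prints:

```
compensation: 0.616 (95% CI 0.147-1.092, n=10)
repeatability_female: R=0.579 (95% CI 0.144-0.803)
repeatability_male: R=0.832 (95% CI 0.454-0.937)
```

The compensation estimate says that in this small simulated study each
percentage point of missing male attendance was made up by ~0.62 points of
extra female attendance (the generator's configured truth is 0.62; ten
nests give a wide CI). The repeatabilities say that nests differ
consistently from each other in their day-to-day attendance. The run
directory also holds `nest_summary.csv`:

```
nest_id  n_days_included  overall_attendance  female_attendance  male_attendance  uniparental
   N001                7               0.794              0.715            0.079        False
   N002                4               0.762              0.762            0.000         True
   N003                2               0.871              0.708            0.163        False
   N004                6               0.933              0.884            0.049        False
   N005                2               0.844              0.747            0.097        False
```

plus hourly/daily attendance tables, bout and gap tables, per-night longest
female night bouts, night interval exports, and `models_report.csv` with
the coefficient estimates and credible intervals of the full model suite.
`lapwing actogram` renders the classic one-row-per-day raster of a nest,
coloured by state with nights shaded.

The same machinery is available as a library:

```python
from lapwing import synthetic, pipeline, models

study = synthetic.simulate_study(synthetic.SimulationConfig(n_nests=60, seed=1))
results = pipeline.analyze(study.events, study.windows, study.metadata)
comp = models.compensation(results.nests, seed=1)
```

## Layout

| module | role |
| --- | --- |
| `lapwing.io` | event/window/metadata CSV model, readers, writers, validation |
| `lapwing.solar` | sun elevation, sunrise/sunset, −6° night intervals, night fractions |
| `lapwing.segmentation` | bouts, exchange gaps, recesses; per-second oracle; quality exclusions |
| `lapwing.aggregation` | hourly/daily/nest attendance tables with inclusion filters |
| `lapwing.models` | harmonic designs, WLS/REML fits, posterior CIs, ICC, compensation |
| `lapwing.synthetic` | alternating-renewal study generator with stored ground truth |
| `lapwing.pipeline` | orchestration, YAML config, run directories |
| `lapwing.plotting` / `lapwing.cli` | actograms and the `lapwing` command |

See `docs/methods.md` for the statistical details, simulator design, and
known limitations.
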