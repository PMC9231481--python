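# cogbattery

A headless, scriptable cognitive test battery for visual attention and
memory. The package is aimed at researchers who work with (or build on)
browser-based cognitive assessment: it reproduces the trial schedules of
seven classic tasks exactly as they are run with human participants,
simulates synthetic cohorts with known latent structure, scores sessions,
and runs the standard benchmark analyses — Bayesian performance
estimation, cross-day test-retest reliability, and latent factor analysis
— entirely from the command line or from Python, with no browser, server
or human data required.

## The battery

Seven tasks, with stimulus geometry in degrees of visual angle and the
standard per-condition trial counts:

| task | measure | conditions |
|---|---|---|
| multiple-object tracking (MOT) | fraction of 5 targets among 10 discs tracked for 8 s on a 12°×12° canvas | speed 1, 4, 8 deg/s |
| enumeration | exact count of 0.5° circles flashed for 50 ms in a 5° region | set size 5–9, 20 trials each |
| load-induced blindness (LIB) | peripheral Gabor contrast detection (0.8 vs 0.4) under foveal cross-length load; peripheral trials gated on a correct foveal response | eccentricity 3° / 6°, 20 trials each |
| go/no-go | hit rate, false-alarm rate and RT for the probe after the cue digit 7 (go iff probe = 3) | 18 go + 18 no-go |
| task switching | cued odd/even vs higher/lower-than-5 judgments; switching cost = RT(switch) − RT(repeat) on correct trials | 20 practice + 30 per task |
| spatial span (Corsi) | forward reproduction of a flashed cell sequence on a 4×4 grid | length 4–8, 12 trials each |
| memorability | repeat detection in a 120-image stream: 40 targets shown twice (8 at distance 100–109, 32 at 2–5) + 40 fillers | 2 blocks (bedroom, kitchen) |

## The analyses

**Bayesian estimation.** Per-condition accuracy uses a binomial likelihood
with a Uniform(0, 1) prior, so the posterior is Beta(1+k, 1+n−k); it is
sampled exactly (default 10,000 draws) and summarized by the mean and the
2.5/97.5-percentile credible interval. Mean RT uses a normal likelihood
with a flat prior truncated to [0, 1000] ms. Group posteriors are the
draw-wise average of the individual posteriors.

**Reliability.** Task-level Pearson r between days, Bland–Altman
agreement on probit-transformed accuracies (limits of agreement at
mean ± 1.96 SD, day 2 − day 1 positive), and per-condition posterior
difference distributions (day 2 − day 1 for accuracy, day 1 − day 2 for
RT, so positive always means second-day improvement) with 95%
highest-density intervals and a count of conditions whose HDI contains
zero.

**Latent factors.** 23 variables (probit-transformed rates with the
1/2N boundary correction; RT and switching cost in ms) over
participant-day observations, z-standardized, decomposed with PCA
(k = 6 by default, full scree always emitted) and FastICA, and grouped by
average-linkage hierarchical clustering on the 1 − |cos| distance between
loading vectors.

**Cohort simulator.** Synthetic participants carry per-task latent
abilities (logit scale), a log-RT baseline and a switch-cost parameter;
P(correct) = logistic(ability − difficulty), RTs are lognormal.
Abilities can follow a planted low-rank factor structure, which makes
factor-recovery testable end to end.

## Worked example

```
cogbattery demo --seed 1 --n 12 --out demo_out
```

simulates a 12-participant, two-day cohort (168 sessions, 14,064 trials),
scores it, and writes every report table. It prints:

```
demo complete: 168 sessions, 22/23 stable conditions, top-6 PCA variance 82.2%
```

meaning that 22 of the 23 condition-level cross-day difference HDIs
contain zero (the simulated cohort has no day effect, so ~95% of
conditions should look stable — repeating the battery alone does not
improve performance), and the first six principal components explain
82.2% of the variance of the 24 × 23 feature matrix. `demo_out/` then
contains, among others, `pearson.csv`:

```
task,pearson_r
corsi,0.8860921088042094
enumeration,0.8780909019150456
gonogo,0.8369700882634605
...
```

(the cross-day correlation of each task's scalar accuracy), the
group-level posteriors per condition and day (`posteriors.csv`), the
cross-day difference table (`crossday_differences.csv`), the PCA/ICA
loadings, the scree, and a `manifest.json` recording seeds, row counts
and the config hash.

The same stages are available piecemeal (`generate`, `simulate`, `score`,
`bayes`, `reliability`, `factors`), and everything is importable from
Python (`cogbattery.schedules`, `.cohort`, `.scoring`, `.bayes`,
`.reliability`, `.latent`, `.battery_io`).

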