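# Methods

This note documents the models, defaults and design choices behind
cogbattery, in the order data flows through the package.

## Trial schedules

Every generator is a pure function of its parameters and an integer seed
(numpy `default_rng`), so schedules are reproducible byte for byte. All
geometry is stored in degrees of visual angle, origin at the screen
center, y upward; pixel conversion is deliberately out of scope.

**MOT.** Ten discs (diameter 1.2°) on a 12°×12° canvas, five cued as
targets; motion lasts 8 s at a constant speed of 1, 4 or 8 deg/s.
The frame rate is not part of the task definition, so it is a parameter
(default 60 Hz). Discs reflect specularly off the four walls — computed
in closed form by folding the free-flight trajectory with a triangle
wave, which keeps each disc (center bounded by the half-canvas minus the
disc radius) exactly on a constant-speed polyline — and may occlude one
another; there are no disc–disc collisions. Initial positions are
uniform with ≥ 1.2° center separation so the cued display is legible.
Because per-frame displacement equals speed/frame-rate except at bounce
frames, the speed is recoverable from a stored trajectory as the median
per-frame displacement × frame rate, which the validator uses as an
energy check. The number of MOT trials per speed is not fixed by the
task description; the battery default is 10 per speed (50 target
scorings per condition, comparable to the 20-trial conditions of the
other tasks) and it is configurable.

**Enumeration.** 5–9 circles of 0.5° diameter placed by rejection
sampling uniformly in the 5° region (circles fully inside), with pairwise
center distance ≥ 0.5° so no two circles overlap; the sampling budget is
explicit and exhausting it raises an error naming the budget.

**LIB.** The foveal cross has one 0.5° and one 1.0° arm (long axis
random); four Gabors (σ = 0.7°, 2.2 cyc/deg) sit on the diagonals at 3°
or 6° eccentricity — the diagonal arrangement is the package's reading of
the dual-task display — and exactly one carries contrast 0.8 among 0.4.

**Go/no-go.** Each trial's stream is 2–5 filler digits (≠ 7), the cue 7,
then the probe; go iff probe = 3, and no-go probes exclude both 3 and 7.
The 50/50 go/no-go balance is implemented as an exact count (18 + 18 by
default), not Bernoulli, so session composition is deterministic. The
per-trial stream structure (filler count, exclusion of 7 among fillers)
makes scoring unambiguous for a continuous-stream task.

**Task switching.** Cues: blue diamond → odd/even (odd→F, even→J); red
square → higher/lower than five (higher→F, lower→J); digits 1–4, 6–9.
The main phase has exactly 30 trials per cue in random order (expected
~50% switches; the switch/repeat ratio is not fixed by design), preceded
by 20 practice trials with i.i.d. cues. Switch status is derived post
hoc from the realized cue sequence; the very first trial has no defined
status and practice trials are flagged and excluded from all scoring.

**Corsi.** Sequences of 4–8 distinct cells (classic convention: no
repeats within a sequence) on the 4×4 grid, 12 trials per length,
pseudo-randomly interleaved.

**Memorability.** One block = 120 presentations: 40 targets twice, 40
fillers once; 8 targets repeat at index difference 100–109 and 32 at
2–5 ("distance" is defined as the difference of the two presentation
indices). The scheduler places long-distance pairs first, then short,
each by sampling uniformly from the currently feasible slot pairs, then
fills fillers; dead ends trigger a restart (budget 1,000), which succeeds
on ≥ 99% of seeds. Because real photographs cannot ship with the
package, a synthetic catalog (`make_synthetic_catalog`) provides image
IDs with nominal hit rates drawn uniformly from the intermediate window
[0.60, 0.70]; any catalog with ≥ 80 annotated images per category works.

## Cohort simulator

The simulator exists to make every downstream stage testable, not to be
a cognitive process model (no drift-diffusion, no age curves). Each
participant has one latent ability per condition family (logit units,
population N(0, 1) by default), a log-RT baseline
`speed_mu = log 450 − 0.15 · a_speed`, a lognormal dispersion σ = 0.25,
and a switch cost `150 − 50 · a_speed` ms added to switch-trial RTs
(positive in expectation, with the large individual spread typical of
task-switching data).

Accuracy: P(correct) = logistic(ability − difficulty + day shift). The
difficulty table is strictly monotone within each task and chosen so a
median participant spans roughly the ranges adult norms show for these
paradigms (e.g. enumeration 0.90 → 0.50 across set sizes 5–9, tracking
0.90 → 0.45 across speeds, span 0.88 → 0.23 across lengths 4–8, LIB
around 0.35–0.45 — most peripheral targets missed). Memorability hits
use logistic(logit(image hit rate) + ability + day shift − 0.5 · [long]),
so long-distance hit rates sit below short-distance ones by default;
false alarms use a base rate of 0.15 modulated by ability. MOT responses
are Binomial(5, p) correct targets per trial; Corsi is all-or-nothing
sequence recall; LIB foveal accuracy defaults to 0.9 and peripheral
responses on foveal-error trials are not recorded, mirroring the task's
gating rule. The day effect defaults to zero on both days — the null
case every reliability test builds on.

Optionally the family-ability vector is `L · t + ε` with k planted
latent traits (unit variance; uniform by default so ICA stays
identifiable) and configurable noise. What passing planted-recovery
tests shows is that the pipeline recovers structure *of the kind it
assumes*; real data carry response biases, learning, lapses and
non-logistic psychometric functions that the simulator does not emulate,
so simulation results bound implementation correctness, not empirical
validity.

## Scoring

Accuracy per condition for enumeration, LIB (peripheral n never exceeds
the foveal-correct count), MOT (per-target partial credit, k over
5 × trials — accuracy read as "how many objects can be tracked"), and
Corsi. HR/FAR for go/no-go (over go / no-go trials) and memorability
(over second / first presentations, HR optionally split short vs long).
Mean RT is over correct trials only; no outlier trimming by default (a
cutoff is configurable). Switching cost = RT(switch) − RT(repeat) per
task type on correct main-phase trials. The task-level scalar used for
Pearson r and Bland–Altman is the unweighted mean of condition accuracies
(overall proportion correct for the two signal-detection tasks, where
per-condition accuracies are not defined symmetrically).

## Posterior estimation

Accuracy: Uniform(0,1) prior × binomial likelihood gives Beta(1+k,
1+n−k) exactly, so the package samples the conjugate posterior directly
instead of running MCMC on the same model — the target distribution is
identical and needs no warm-up or convergence diagnostics. A generic
random-walk Metropolis sampler for the same model ships alongside and is
used only as an independent oracle in tests. RT: normal likelihood for
the mean with the sample SD plugged in as known σ and a flat prior
truncated to [0, U], U = 1000 ms by default (the bound is exposed in
config, and a warning is logged when the sample mean exceeds 0.9·U,
since slow participants — e.g. memorability RTs near 900 ms — can be
pulled down by the truncation). Group estimates average the individual
draws draw-wise. Cross-day contrasts are draw-wise differences, sign
convention improvement-positive; their interval is the 95% HDI computed
by shortest-interval search on sorted draws (percentile and HDI agree
for symmetric posteriors). The default draw count is 10,000; pipeline
and replicate studies use 2,000 draws, which changes interval endpoints
by well under the widths involved.

## Reliability

Pearson r on task scalars; Bland–Altman on probit-transformed task
accuracies (diff = day 2 − day 1, limits at mean ± 1.96·SD, ddof = 1),
with a raw-scale variant available; and the count of conditions whose
cross-day HDI contains zero. The condition battery defaults to the same
23 variables as the latent analysis and is config-driven.

The null-coverage study (`null_coverage_simulation`) checks that with no
day effect ~95% of condition HDIs contain zero. It simulates replicate
cohorts at the count level: per-participant success probabilities from
the default population, per-condition binomial counts at the battery's
standard trial numbers, conjugate posteriors, draw-wise group averages,
HDIs — trial-wise Bernoulli responses and a binomial draw of k are the
same distribution, and the count-level path keeps 200 replicates × 23
conditions tractable on one CPU. RT-condition posteriors there use the
untruncated normal form of the truncated posterior (means sit hundreds
of SDs from the [0, 1000] bounds, so the truncation mass is nil).

## Latent factors

Rates are probit-transformed with the 1/2N boundary correction
(0 → 1/2N, 1 → 1 − 1/2N); RT and cost variables stay in ms. Columns are
z-standardized with the sample SD (ddof = 1) so the covariance of the
standardized matrix *is* the correlation matrix, making PCA equal to its
eigendecomposition exactly; constant columns are left unscaled with a
warning. The 23-variable set — enumeration accuracy ×5, MOT accuracy ×3,
LIB accuracy ×2, span accuracy ×5, memorability HR-short/HR-long/FAR,
go/no-go HR/FAR/go-RT, switch cost ×2 — is the package's reconstruction
of the analysis variables consistent with the battery's condition
structure, and is exposed as `latent.FEATURE_COLUMNS` for users to
re-define. Observations pool both days as separate rows; rows missing
any variable are dropped with a warning.

PCA loadings are the unit-norm eigenvectors (orthonormal; components
ordered by explained variance); the full scree is always emitted and
k = 6 is only a default — no automated elbow detection is imposed.
FastICA (scikit-learn) runs on the same matrix with k components;
component order is meaningless and each component's sign is normalized
so its largest-magnitude loading is positive. Because the fixed-point
iteration can stall on small matrices, `fit_ica` accepts a restart count
(consecutive derived seeds, keeping determinism); non-convergence raises
an error naming the budget. Components whose recovered source is nearly
Gaussian are unidentifiable in principle; the per-component |excess
kurtosis| is attached so users can flag them. Variables are clustered by
average linkage on 1 − |cosine| of loading vectors — the absolute cosine
makes sign-flipped loadings neighbors, which is the right notion of
"loads on the same factors"; neither the linkage nor the metric is fixed
by convention elsewhere, so both are documented here as package choices.

## Files, configuration, determinism

Schedules serialize to JSON Lines ({task, trial_index, condition,
payload}); sessions to a tidy CSV with a pinned 20-column header (bools
as `true`/`false`, floats via `repr`, so write→read→write is
byte-identical); scores and summaries to fixed-header CSVs. Writes are
atomic (temp file + rename) and parse errors carry line numbers. The
config document (YAML/JSON) defaults to the battery's standard
parameters, rejects unknown keys, and auto-fills missing seeds with a
log line; every CLI run's manifest records the config hash, seeds and
row counts per stage. All randomness flows through explicitly seeded
generators — there is no global RNG state anywhere in the package.

## Problem sizes used in the shipped checks

The test suite and acceptance script use: 8–12-participant cohorts for
unit and round-trip tests, 50 participants for the trend checks, 100
participants (200 observations) for planted two-factor recovery, 200
replicate cohorts × 23 conditions × 2,000 draws for the null-coverage
study, and 2,000 enumeration layouts / 1,000 memorability seeds for the
constraint-satisfaction checks. These sizes were chosen so the whole
suite completes in a couple of minutes while keeping every statistical
assertion comfortably inside its sampling error.

## Known limitations

Rendering, stimulus timing, monitor calibration and gamma correction are
out of scope — the package produces and analyzes schedules and
responses, not pixels. The simulator's response model is a convenience,
not a theory (see above). The RT prior's upper bound can bite for slow
tasks if left at 1000 ms. Signal-detection modeling (d′/criterion),
hierarchical pooling across participants, ICC/Cronbach reliability
variants and factor rotation are deliberately not implemented.
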