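# Methods

`pupilverse` implements a multiverse analysis of event-related infant
pupillometry: one recording is expanded into every dataset a set of
plausible preprocessing choices could have produced, two competing
regression models are fitted to each dataset, and the stability of the
condition effect is reported across the whole lattice instead of for a
single pipeline. This note documents the models, the synthetic-data
generator, the numerical choices, and the known limitations.

## The preprocessing lattice

Five choice points ("researcher degrees of freedom") are crossed:

| step | choice | levels |
|---|---|---|
| 1 | extreme values | keep all / keep only 2 mm < pupil < 8 mm (strict) |
| 2 | gaze filter | whole screen / closed AoI rectangle only |
| 3 | gaps | drop missing samples / linearly interpolate interior gaps |
| 4 | baseline window | first 16 / 100 / 200 ms of each trial |
| 5 | participants | keep all / exclude > 30% missing (strict) |

yielding 2 x 2 x 2 x 3 x 2 = 48 datasets. Operators run in the fixed
order above: eyes are averaged first (a sample is missing if either eye
is), filters mark samples missing rather than deleting rows, gap handling
resolves missingness, the per-trial subtractive baseline uses the median
of observed samples with `t_trial < window`, and participant exclusion
runs last. Per-participant missingness is measured after the filters but
before gap handling, so the >30% flag is fork-specific. Trials with no
observed sample in their baseline window are dropped. Divisive baselining
(`y = pupil / baseline`) is implemented as an off-lattice option; the
lattice itself uses the subtractive form throughout.

Two consequences of this design are worth stating explicitly because
they shape everything downstream:

* **Per-trial subtractive baselining removes any constant condition
  offset.** If the visual block sits a constant `beta` above the
  audiovisual block, the trial baseline contains the same `beta` and the
  corrected series does not. Only the *time-varying* part of the
  condition difference survives (relative to its own baseline-window
  value). Constant-effect recovery is therefore assessed on the
  uncorrected signal (see "Validation" below), and block-coefficient
  estimates from baseline-corrected datasets should be read as
  within-trial drift contrasts, not tonic offsets.
* **Baselining correlates errors within a trial.** Subtracting a noisy
  per-trial baseline adds one shared error term to every sample of the
  trial. Neither candidate model contains a per-trial variance
  component, so Wald intervals for the block coefficient are
  anti-conservative on baseline-corrected data (see "Limitations").

## The two candidate models

Both models are penalized Gaussian regressions of the corrected pupil
change `Y` fitted by minimizing

    ||y - X theta||^2 + sum_j lambda_j theta' S_j theta.

**Time model** — `Y = a + b*X + f_X(t) + f_id(t) + e`:

* `X` is the familiarization-block indicator (visual = 1), so `b` is the
  Visual - Audiovisual contrast;
* `f_X(t)`: one cubic B-spline smooth of trial time per block level
  (k = 20 basis functions, equally spaced interior knots, second-order
  difference penalty, one smoothing parameter per block). Each smooth is
  sum-to-zero constrained over the data, which keeps `b` interpretable
  as the mean condition difference;
* `f_id(t)`: one k-basis smooth of trial time per participant — a factor
  smooth. All participants share one wiggliness penalty and one
  additional ridge penalty on the difference-penalty null space
  (constant + linear), making the term a proper random-curve analogue
  that can absorb participant-level offsets and trends. These smooths
  are deliberately *not* sum-to-zero constrained: constraining them
  leaves participant offsets in the residual while the competing model's
  cell means absorb them, which inverts the model comparison for
  structural rather than scientific reasons.

**No-time model** — `Y = a + b*X + u_(X,id) + e`: the smooths are
replaced by one ridge-penalized coefficient per participant x block
cell (shared smoothing parameter), i.e. random cell means with no time
structure.

Smoothing parameters minimize the GCV score `n RSS / (n - edf)^2` over a
13-point log-spaced grid (1e-4 to 1e8) by coordinate descent: each
penalty group is optimized over the grid in turn, sweeping until the
score changes by less than 1e-6 (relative) or 25 sweeps. `edf` is the
trace of the hat matrix. A `ModelSpec(participant_smooths=False)`
variant drops the factor smooths, giving a population-level time model
whose design is full rank without penalties (used by the least-squares
equivalence checks; the factor-smooth design is intentionally rank
deficient at zero penalty, like any random-effect structure).

Model comparison uses

* `BIC = -2 l(theta_hat) + k log(n)` with the Gaussian log-likelihood at
  the ML residual variance and `k = edf + 1` (effective degrees of
  freedom plus the residual scale — penalized models have no integer
  parameter count, so the surrogate must be documented: BIC deltas
  depend on it). Delta-BIC evidence bands: < 2 weak, 2-6 positive, 6-10
  strong, > 10 very strong.
* adjusted `R^2 = 1 - (RSS/(n - edf)) / (TSS/(n - 1))`, clipped to
  [0, 1].

Uncertainty is Wald/normal throughout: coefficient covariance
`sigma^2 (X'X + sum lambda_j S_j)^-1`, z-quantile CIs. The
condition-difference smooth is `diff(t) = b + f_visual(t) -
f_audiovisual(t)` on a 101-point grid over the observed trial window,
with pointwise SEs from the joint coefficient covariance and significant
windows reported as maximal runs of grid points whose CI excludes zero.
The time covariate is trial time by default; block time is available via
`ModelSpec(time_scale="block")`.

Datasets in which a participant retains fewer than 10 rows drop that
participant from the fit (with a warning); datasets with fewer than two
participants or a missing block level are recorded as fit errors, and
degenerate (empty) datasets stay visible in the lattice as flagged gaps.

## The synthetic-data generator

The generator emulates a 60-Hz binocular familiarization session: two
blocks (audiovisual, visual) of nine consecutive 1-s trials per
participant. The latent signal is

    latent(p, block, t) = tonic_p + r(t)
                          + 1[visual] * (beta_true + diff_curve(t))
                          + f_p(t)

with participant tonic levels `N(4.0, 0.3^2)` mm, a common event-locked
within-trial response `r(t)` (default: linear decline of 0.4 mm over the
trial — the familiarization signature both blocks share, and the
dominant time structure of such recordings), a condition effect split
into a constant `beta_true` (default 0.05 mm) plus a zero-mean
early-positive/late-negative time course (default 0.25 mm sine over the
trial), and smooth zero-mean per-participant random curves (random
degree-3 Legendre combinations, SD 0.2 mm). Both eyes observe the latent
signal plus correlated white noise (SD 0.15 mm, left/right noise
correlation 0.9), reproducing the near-unity empirical left/right pupil
correlation used as a sanity check on real recordings.

Artifacts are injected on top:

* **blinks**: Poisson (0.1/s) short binocular missing runs of 100-400 ms;
* **trackloss**: longer runs (600-2000 ms), monocular half of the time,
  budgeted per participant x block to a mean 12% of samples with a
  lognormal per-participant multiplier (sigma 0.25) — data quality
  varies between infants, and designated participants receive extra
  binocular trackloss until they exceed the 30% exclusion cutoff;
* **extreme yet plausible values**: sustained 200-1000 ms excursions
  during which the tracked value sits just outside the physiological
  band (8.1-8.8 or 1.3-1.9 mm). Extremes are runs, not isolated samples,
  because pupil size cannot jump several millimetres within one 60-Hz
  frame; about 1% of samples are affected.

Gaze points fall inside the AoI with probability 0.9 (uniform within it)
and uniformly over the rest of the screen otherwise. The default screen
is a 27-inch 16:9 panel at 109 ppi viewed from 60 cm (2560 x 1440 px);
the AoI is the central 10 deg x 10 deg stimulus (~450 px) plus a 1-cm
(~43 px) margin. All randomness flows from a single integer seed.

Defaults were chosen so that a default session reproduces the
qualitative features of a real infant familiarization recording:
overall missingness around 20%, a distinct minority of participants
above the 30% cutoff, blink-coupled extreme values, and time structure
strong enough that time-aware models dominate mean-only models in every
dataset of the lattice.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: autocorrelated (drifting) measurement
noise, luminance- or gaze-angle-dependent pupil changes
(pupil-foreshortening error), saccade/fixation dynamics, block-scale
habituation trends beyond the per-trial response, and missingness that
is informative about attention. Recovery and calibration results here
certify the estimation machinery under the generator's assumptions, not
the field validity of any preprocessing choice.

## Validation strategy

* Row counts, determinism, injected rates, and the left/right
  correlation are checked directly against the generator's closed forms.
* The B-spline basis is compared to an independent Cox-de Boor
  recursion; penalized fits at zero penalty are compared to
  normal-equations least squares (1e-8 relative).
* Parameter recovery: with `beta_true = 0.1` mm and the shaped
  difference curve, 100 artifact-free replications fitted on the
  *uncorrected* signal recover the coefficient without bias (within 3
  Monte-Carlo SEs) with 90-99% CI coverage, and the difference smooth
  correlates > 0.8 with the true curve.
* Model selection: on a default 8-participant session the time model
  attains the lower BIC in >= 46 of 48 datasets and the higher adjusted
  R^2 in all of them.
* Problem sizes (8 participants for lattice runs, 6 for recovery
  replications, 3 seeds for the null study) keep a full validation run
  in the low minutes on one CPU while leaving every structural count
  (48/96) at study scale.

## Known limitations

* **Null calibration of spec-curve significance fails by design of the
  analysis, and the corresponding check is expected to stay red.** Under
  a true null, ~25-35% of specification-curve points are flagged
  significant at the nominal 5% level. The cause is structural, not a
  bug: per-trial baselining injects a trial-level shared error, the
  models contain no trial random effect, and iid-based Wald SEs are
  therefore too small on baseline-corrected data. Fixing it would
  require per-trial random intercepts or autocorrelation-aware errors,
  which are outside this package's model set (the no-baseline recovery
  checks show the intervals are well calibrated when the model is
  correctly specified). Spec-curve significance flags should be read as
  descriptive colouring, and BIC/R^2 comparisons — which are unaffected
  — as the primary inferential output.
* GCV occasionally undersmooths relative to REML-type criteria; the
  lambda grid bounds (1e-4, 1e8) are wide but finite.
* The factor-smooth construction shares one wiggliness and one
  null-space penalty across participants; it is the minimal random-curve
  structure, not a replication of any specific mixed-model software.
* `R^2` is clipped to [0, 1]; severely misspecified fits report 0
  rather than a negative adjusted value.
* The 16-ms baseline window contains a single 60-Hz sample; with
  extreme values retained (step 1 = keep all), that sample can sit on an
  artifact excursion and shift a whole trial. This is a faithful
  property of single-frame baselines, and it is why the `all|*|*|16|*`
  corner of the lattice is the least stable.
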