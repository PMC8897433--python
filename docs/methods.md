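# Methods

## The system and the data streams

A trial stretches a self-assembled army-ant bridge by opening a terrain
gap 1 mm every 30 s up to 30 mm and then closing it at the same rate:
31 expansion intervals (gap 0…30 mm) followed by 30 contraction
intervals (29…0 mm), 61 gap intervals in all. Each trial yields three
data streams, which `antbridge.trial_io` represents and round-trips as
plain CSVs:

* a per-second structural series — gap (mm), phase, bridge volume
  (mm³), number of ants, mean cross-sectional area (mm²), tautness
  (relative height of the side-view center of mass; lower = slacker),
  and a broken flag;
* timestamped joining/leaving events (total joins equal total leaves,
  because every bridge starts and ends empty);
* per-10-s optical-flow readings (px/frame) for the bridge and the two
  adjacent platforms.

Seconds flagged broken (the bridge collapsed or was recovering) are
excluded from every statistic. Trials broken for more than half their
span are excluded from fitting entirely. Broken spans are stored both
as `[start, end]` metadata and as the per-second boolean; downstream
code consults only the boolean.

## Event-count models

All event counts per 30-s gap interval are modeled as negative binomial
with mean µ and dispersion θ (variance µ + µ²/θ); this NB2 convention
is fixed package-wide and all fitting/drawing converts internally.
`nb_draw` treats θ = ∞ as the Poisson limit; fitted dispersions that
reach the Poisson boundary are capped at 10⁶.

Three simulation models share one discrete-time loop
(`antbridge.simulator`): the bridge starts empty at gap zero; each
interval's joins and leaves are drawn from the state at the interval's
start; executed leaves are clamped so the count never goes negative.

* **Baseline** — per-phase NB distributions. The field estimates are
  µ/θ = 1.13/1.33 (join) and 0.67/1.98 (leave) in expansion, 0.33/0.65
  and 1.04/8.10 in contraction (`field_nb_models()`), giving a mean net
  gain of 0.46 ants/interval while expanding and a net loss of 0.71
  while contracting.
* **Delay** — leave *decisions* are drawn each interval and executed
  d intervals later (d ∈ [1, 6]; queue empty at the start, so there are
  no phantom pre-trial decisions). Because observed early-contraction
  leaving events would then reflect late-expansion decisions,
  `apply_delay_reassignment` recounts leaves in the first d contraction
  intervals as expansion events and refits both leave distributions;
  joining is never delayed. Serialized delay models carry a
  `refit_delay` tag and loading rejects a d that disagrees with it.
* **Accumulator** — event rates respond to the deficit
  Δ = ρ\*·g − N (positive = too few ants): µ = exp(α + βΔ), drawn NB
  with a kind-specific θ. ρ\* (ants per mm of gap) is the packing
  density at which joining and leaving are equally likely. The
  equilibrium count ρ\*·g is kept real-valued; N is an integer.

### Fitting

* `fit_nb_counts` fits each trial by maximum likelihood (µ̂ is the
  sample mean; θ̂ maximizes the profile likelihood, bounded in
  [10⁻⁴, 10⁶]) and returns across-trial medians of µ and θ. The median
  is order-invariant and robust; trials whose θ is inestimable
  (all-zero counts) are dropped from it with a warning.
* `estimate_equilibrium_density` fits pooled logistic regressions of
  per-interval event *occurrence* (≥ 1 event, not the count) on packing
  density N/g, excluding zero-gap intervals, and solves for the density
  where the two linear predictors cross (Brent root-finding bracketed
  by the observed density range; the grid brute force agrees to 10⁻³).
  Trials are pooled without a trial effect. Non-crossing curves raise a
  no-equilibrium error that carries both fits.
* `fit_deficit_regression` regresses per-interval counts on the
  start-of-interval deficit with a log-link NB model (statsmodels NB2;
  θ = 1/α̂ is a single global estimate per event kind).
  `deficit_dispersion_diagnostic` reports binned mean squared Pearson
  residuals across Δ to check the constant-θ assumption.

The accumulator intercepts are not published and must be refit from
data. `example_accumulator_model()` combines the published slopes,
dispersions, and ρ\* with intercepts α_j = α_l = log(0.6): the rates
balance exactly at equilibrium with 0.6 expected events per interval —
inside the observed 0.33–1.13 range — which makes the example
self-regulating around ρ\*·g. It is an illustrative default, not a
field estimate.

### Simulation details and open choices

* *Within-interval ordering*: joins apply first; leaves are clamped to
  `N_start + joins` (the least restrictive rule consistent with
  non-negative counts). The pre-clamp draws are stored on every
  trajectory, and a `clamp="before_joins"` variant is available, so
  alternatives can be replayed.
* *Vibration phase* (gap alternating 29/30 mm after full expansion,
  default 60 intervals = 30 min; the original duration is not stated):
  the linear models use contraction parameters on gap-decreasing
  intervals and expansion parameters on gap-increasing ones — they are
  defined only per phase, and this matches their premise of responding
  to every shift. The rule is configurable (`vibration_rule`). The
  accumulator needs no rule: Δ barely moves, so neither do its rates.
* *Scaled/rate protocols* reuse the same geometry with a different
  maximum gap (30/60/90 mm) or step size (e.g. 0.5/1/2 mm per 30-s
  interval); event models stay "per interval", since that is how they
  are defined.
* `run_experiment` spawns per-simulation seeds from one
  `SeedSequence`, so experiments are bit-reproducible, and reports the
  mean trajectory, per-run hysteresis extents, fractions
  negative/positive, and — for vibration schedules — the fraction of
  runs leaving the 5–25-ant band and the fraction reaching zero ants
  during vibration.

## Extent of hysteresis

For one trial or simulated run, the metric (ant count, volume, …) is
plotted against gap size separately per phase and each phase is
smoothed by LOESS: tricube-weighted local quadratic regression using
the nearest `floor(span·n)` samples (span 0.75 by default, matching the
classical implementations; verified against R's `loess` to 10⁻¹²).
Curves are evaluated every 0.5 mm across the overlap of the two
phases' gap supports; gaps visited in only one phase contribute
nothing. The extent is

    extent = ± area_between / max(area_expansion, area_contraction)

with trapezoidal integrals, negative when the expansion curve's area is
larger. The ratio is capped at 1 (wildly crossing curves can otherwise
exceed it); identical curves give 0, and two identically-zero curves
give NaN with a reason. Because the smoother is linear in the
responses, batch experiments smooth thousands of trajectories with two
precomputed matrices. The span is a configuration knob: simulation
statistics move by well under the reported tolerances between spans
0.5 and 0.75. A no-smoothing (per-gap means) variant is provided.

`hysteresis_ttest` is the one-sample, two-tailed t-test of per-trial
extents against zero, with a 95% t-interval; zero-variance inputs are
flagged degenerate rather than tested.

## Performance and cue resampling

Bridge *performance* is the signed residual from a per-trial
least-squares regression of bridge optical flow on platform flow —
by default on the *sum* of the two platform flows; a two-covariate
variant is available since the original description does not
disambiguate. Residuals are mean-zero per trial by construction;
broken flow intervals are excluded.

`resample_null` asks whether a cue (performance, or tautness for
leaving) is elevated or depressed in the window (default 10 s) before
events of one kind, within one phase (phases are analyzed separately to
remove phase as a confounder). Each second inherits the performance of
its containing 10-s flow interval; an event contributes the mean over
`[t − w, t)`, and events whose window touches a broken period or
precedes coverage are dropped. The null redraws each trial's event
times uniformly without replacement from that trial-phase's candidate
seconds (non-broken, in-phase, fully usable window) and recomputes the
pooled mean, 10,000 times by default. Significance is the central-95%
rule; the two-tailed p is 2·min(tail fractions) clipped at 1.
`window_sensitivity` repeats the test across window lengths, and
`event_timing_uniformity` checks event offsets within their 30-s
interval against Uniform(0, 30) by a Kolmogorov–Smirnov test (events
directly triggered by gap adjustments would pile up at the start of
intervals).

*Known limitation*: the null treats event seconds as exchangeable.
When event counts per interval are overdispersed (θ ≈ 1), events
cluster in time while the cue series is autocorrelated over ~20 s, so
the observed mean is slightly overdispersed relative to the null and
the central-95% rule becomes mildly anticonservative (≈10% type-I at
small trial counts in our synthetic checks, vs 5.0% when event timing
is exchangeable). This is a property of the uniform-randomization
design itself; the calibration test therefore uses a near-Poisson
generating model, and borderline real-data verdicts should be read
with this in mind.

## Synthetic data generator

`antbridge.synthetic_data` generates trials with the statistical
structure the analyses assume, so fitting, hysteresis, and cue code can
be exercised end to end with known ground truth. Defaults mirror the
study conditions: ten trials on the 61-interval schedule; events
simulated from the example accumulator model (real bridges are
density-regulated; any `ModelSpec` can be substituted) and placed at
uniform offsets within their interval, consistent with the observed
timing uniformity.

Dressing of the ant-count trajectory:

* volume = 57 mm³/ant · N + Gaussian noise, with the noise scale set to
  hit a target volume–ants correlation (default 0.93, the middle of the
  observed 0.88–0.98 range; 57 mm³ ≈ the observed ~1080 mm³ at ~19
  ants). An unreachable target (no ant-count variance) is an error.
* tautness = 0.5 − 0.02·excess + noise (sd 0.03), monotone in the
  excess −Δ: slack bridges hang lower. This is a phenomenological
  stand-in sufficient for testing the tautness resampler, not a
  mechanical model.
* platform flows follow an AR(1) (mean 8 px/frame, φ = 0.8, sd 1);
  bridge flow = 1 + 0.45·(sum of platforms) + residual (sd 0.8).
  Optional cue injections add a performance boost to flow intervals
  preceding joins, or a tautness drop before leaves.
* optional broken periods (Poisson count per trial, uniform 20–60 s).

Simulated trajectories can end with ants still in the bridge, while
real trials end empty; a forced disassembly tail (the remaining ants
leave over ≥ 30 s after the schedule) balances the totals and is
flagged broken so every analysis excludes it.

What the generator does **not** emulate: spatial structure, traffic as
a process, break dynamics (breaks are just masked spans), and any
dependence of flow on the bridge's actual state beyond the injected cue
effects. Passing tests therefore demonstrate the correctness of the
computational pipeline under its own assumptions, not the field
validity of the models.

## Problem sizes and tolerances

The test suite simulates 3,000 expansion–contraction runs and 1,000
vibration runs for the headline comparisons (Monte-Carlo standard
errors well inside the asserted bands) and 400 synthetic repetitions
for the resampling calibration; `scripts/acceptance.py` uses the full
10,000/1,000 runs. NB recovery tolerances were set from the observed
spread of the median-of-fits estimator at the study's size (10 trials ×
61 intervals). Deficit-regression recovery is asserted on fixed-design
data (counts drawn at given Δ); on dynamically simulated trials the
state–noise feedback attenuates the slopes, so those checks are
sign-and-scale only.
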