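# Methods

This note documents the models, numerical choices and limitations behind
`rdklearn`.  The package simulates and analyzes a multi-day 4AFC
global-motion direction-discrimination protocol in which difficulty is an
adaptive *direction range* on a random-dot stimulus; everything below is
exercised on simulated observers with known ground truth.

## Stimulus model

A trial presents dots in a 5° aperture at 3.5 dots/°² (69 dots), 10°/s,
250 ms lifetime, 500 ms duration.  Only dot *directions* matter downstream,
so the stimulus module samples directions rather than trajectories: each of
the 69 dot slots contributes `duration/lifetime = 2` independent draws (a
respawn re-draws both the direction and the signal/noise identity).  Noise
identity is per-draw Bernoulli(ν) by default — the noise fraction holds in
expectation — with an exact fixed-count variant available
(`fixed_noise_count=True`).  Signal directions are uniform on the closed
interval [θ − R/2, θ + R/2], wrapped modulo 360°; noise directions are
uniform on the circle.  Noise dots re-randomize per lifetime, not per frame;
frame-wise re-randomization would only change the effective number of
independent samples and is not modeled.  Positions, aperture masking and
rendering are out of scope.

## Psychometric model and threshold

Component correctness follows a decreasing Weibull

ψ(R) = γ + (1 − γ − λ)·exp(−(R/α)^β),

with chance γ = 0.5 per component (0.25 for the combined 4AFC judgment) and
lapse λ fixed at 0.05.  The task gets *harder* as R grows, so the decreasing
form keeps R in native units; it is equivalent to the increasing textbook
form on a difficulty axis.  (α, β) are estimated by maximizing the binomial
log-likelihood of per-level counts, in log-parameter space with L-BFGS-B
(ftol 1e-12) from 5 multistarts over a log-spaced α grid spanning
[0.1, 5]× the largest tested range; box bounds are α ∈ [1e-2, 1e5],
β ∈ [0.05, 50].  Levels with zero trials are dropped; no continuity
correction.  Data with fewer than two informative levels, or all-correct /
all-incorrect counts, are reported `converged=False` rather than raising.
Lapse estimation, Bayesian fitting and bootstrap threshold CIs are
deliberately out of scope.

The direction-range threshold (DRT) is the range at which ψ crosses the
criterion midway between chance and the lapse-limited ceiling,
c = ((1 − λ) + γ)/2 (0.725 for components, 0.60 for combined judgments —
the combined chance level of 0.25 is this package's reading of a 4AFC
design).  For the halfway criterion the threshold has the closed form
R* = α(ln 2)^(1/β); unit tests verify the closed form against numeric root
finding to 1e-6 over α ∈ [10, 400], β ∈ [0.5, 6].

At the *session analysis* level, reported DRTs saturate at 360° (the full
circle): when performance never declines over the tested levels — e.g. the
cue-driven horizontal component during audio-visual training — the MLE
threshold is unbounded and the session is reported at ceiling.  The
library-level `fit_weibull` is left uncapped.

## Staircases

Training uses a 2-up-1-down rule on the 10-level grid (0, 40, …, 320,
355°): two consecutive correct responses *at the same level* step one level
harder, one error steps one level easier, any level change resets the
streak.  This is the variant that converges where p² = 1/2, p ≈ 0.7071.
The 320→355° step is treated as one grid step even though it is 35° rather
than 40°.  Levels clamp at the grid ends (the protocol source is silent on
boundaries).  Aborted trials (fixation/head breaks, modeled as a per-trial
probability) leave the staircase exactly as it was and do not count toward
block length.

The post-test runs two such staircases with interleaved trials, one driven
by each component judgment.  Interleaving is strict alternation starting
with the horizontal staircase by default (randomized interleave available
via config + seed); whether the original procedure alternated strictly or
randomly is unknown, and both behaviors are implemented.  Training sessions
start at level 2 (80°) and carry staircase state across days (config flag;
daily reset available); post-test staircases start at the participant's
final training level.  These are package defaults where the protocol source
is silent.

A validation routine drives the controller with a known-ψ observer on a
fine 5° grid and averages the analytic probability-correct at visited
levels; with 20,000 post-burn-in trials this lands within one percentage
point of 70.71%.  Step-size bias of transformed up-down rules grows with
coarse grids, hence the fine grid for this measurement.

## Simulated observers

**Parametric observer.**  Each component judgment is a Bernoulli draw from
ψ at the trial's range; an incorrect component selects the opposite pole of
its axis (each axis has only two poles).  Ground truth is therefore exactly
invertible, which is what parameter-recovery tests need.  Mechanisms:

* *Learning* adds `learn_rate` degrees to α per completed session
  (α_eff at day d uses (d − 1) accrued sessions), matching the linear-slope
  description of learning used in the analysis.
* *Transfer*: at the untrained location only a fraction τ ∈ [0, 1] of the
  accrued learning is expressed; τ = 1 is full spatial generalization,
  τ = 0 full retinotopic specificity.
* *Noise dots* scale the Weibull scale: α_eff = α(1 − ν)^c with c = 1 by
  default.  The mapping from noise fraction to difficulty is a synthetic
  stand-in (nothing in the protocol constrains it); it is monotone
  decreasing, which is all the titration logic requires.  α_eff is floored
  at a tiny positive value so ν = 1 degrades performance to chance instead
  of producing an invalid scale.
* *Auditory cue*: during cued training the horizontal judgment is answered
  from the cue with probability `cue_reliability`, default 1 − λ so lapses
  still occur on cued trials.  The cue is informative about the horizontal
  component only; vertical judgments are unaffected.
* *Aborts* occur with probability `abort_prob` before a response is formed.

**Mechanistic observer.**  Pools the sampled dot directions by circular
mean, adds von Mises(κ) internal noise, and responds with the quadrant
containing the perceived direction (boundary ties broken by the rng).  It
is used to check that a plausible pooling mechanism produces monotone
psychometric behavior of the Weibull type, separating "is the fit correct?"
from "is the model adequate?".

## Day-1 titration

Practice: 20-trial mini-blocks starting at ν = 0.30.  "Maintain a threshold
of at least 80°" is operationalized as the running staircase ending the
block at ≥ 80°; an all-correct block raises ν by 0.10, a failed block
lowers it by 0.10, with a cap of 10 mini-blocks before flagging the
observer as not titratable.  Titration: one 100-trial staircased block, fit
with the Weibull; DRT in [100°, 200°] keeps the setting, otherwise a single
±5-percentage-point adjustment is applied and the protocol proceeds without
re-titration ("accepted" reflects a converged fit; `in_range` records
whether the band was hit without adjustment).  Noise fractions are rounded
to 3 decimals so repeated ±0.05/±0.10 steps stay exact in the logs.

## Cohort simulation and logging

The default population is 8 visual-only (V) and 9 audio-visual (AV)
observers.  Free parameters the protocol cannot constrain were fixed once
at values a practitioner would call realistic for this task family: base
α ~ Normal(260°, 50°) with β = 2 (≈150° baseline DRT at ~30% noise, the
middle of the titration band); vertical learning rates
V ~ Normal(9.5, 2) and AV ~ Normal(6, 2) α-degrees/session (implying
recovered DRT slopes near 5.6 and 3.5 °/day); AV horizontal learning faster
(Normal(12, 3), cue-driven) with τ_h = 0, V horizontal like vertical with
τ = 1.  These produce the qualitative pattern of interest — learning in
both groups, transfer of vertical learning, retinotopically specific
cue-driven horizontal gains — and are config-exposed, not estimates.

Every run descends deterministically from a master seed via
`numpy.random.SeedSequence` spawning (one substream per participant), so a
configuration reproduces byte-identical CSVs.  The trial log has one row
per presented trial (fixed column order, RFC-4180, UTF-8), aborted trials
included but blank-scored; a companion summary CSV holds the per-session
Weibull fits.  A replay routine re-derives every logged staircase
trajectory from the logged correctness alone and is used as a round-trip
test of log fidelity.

## Learning and transfer analysis

Per participant and component, the learning rate is the OLS slope of
session DRT on training day (closed-form slope and SE, verified against the
textbook formula); non-converged sessions are dropped with a count.  Group
rates are means of participant slopes with between-participant SEs — a
deliberate, simpler stand-in for mixed-effects marginal slopes; the trial
log is structured so an external mixed-model analysis can be run on it
unchanged.  An alternative average-DRT-then-fit path is provided
(`method="mean-then-fit"`); the two agree on balanced data.  Retention and
transfer are post-test-minus-last-day DRT differences at the trained and
untrained locations with seeded bootstrap CIs over participants
(B = 2000).  Horizontal-component results under cued training carry a
`cued` flag and should not be read as visual learning rates.

## What the simulations do and do not show

The synthetic cohorts emulate the *structure* of real data — per-trial
logs, staircase dynamics, titration flow, group differences, transfer — but
the observer is stationary within a session, has no sequential
dependencies, fatigue, criterion drift or attention lapses beyond the fixed
λ, and its noise-to-difficulty mapping is invented.  Passing recovery tests
therefore demonstrates that the pipeline is self-consistent (it recovers
what generated the data at realistic trial counts) — not that human data
would satisfy the Weibull or linear-learning assumptions.  Validation
sizes: recovery uses 200 replicates per condition (median fitted DRT within
5% of truth at 300 trials/session; error shrinking monotonically over
75–600 trials); transfer signatures use 20 seeded single-observer
replicates; staircase convergence uses 20,000 trials.
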