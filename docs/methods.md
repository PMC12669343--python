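# Methods

## Generative model of the observer

A virtual observer has two independent ground-truth curves.

**Objective (2AFC accuracy).** A two-part Weibull: flat at the chance level
0.5 for intensities at or below the task threshold θ₁, rising as
`0.5 + (0.5 − λ)(1 − exp(−(x − θ₁)/θ₂))` above it. λ (default 0.02, fixed,
not estimated) models attention lapses and caps the asymptote at 0.98. θ₁
is the quantity every calibration method tries to estimate: the *highest*
intensity at which accuracy is still at chance. θ₂ (intensity units)
controls how quickly performance rises above the shoulder.

**Subjective (visibility).** A logistic CDF with midpoint θ and spread σ,
modelling the probability of a "seen" report after binarising a 4-point
visibility rating (0 = not seen, >0 = seen).

**Trial simulation.** Given an intensity, a trial is correct iff a
uniform(0,1) draw falls below the objective curve, and seen iff an
independent draw falls below the subjective curve. The two outcomes are
conditionally independent given intensity; real observers likely violate
this (visibility and accuracy share trial-level noise), which is one reason
simulation results understate the value of the subjective exemption for
real data.

**Population.** All four parameters (θ₁, θ₂, θ, σ) are drawn independently
from normal distributions truncated to positive support, each with mean 25
and sd 5. This mirrors the mildly informative priors used when fitting such
curves to empirical data; an empirically fitted population would show
correlations between parameters and a wider θ₁ spread, neither of which the
synthetic population reproduces. Consequences are discussed under
*Benchmark interpretation*.

## The STEP controller

Per run: start at the scale maximum (intensity and boundary alike), step
size 32, and iterate propose → observe (correct, seen) → update streak
bookkeeping → boundary test → intensity adjustment → step-size update.

- **Streak bookkeeping.** CWIR(t) counts trailing consecutive errors; a
  correct response closes the open streak, recording its mean intensity and
  triangular weight k(k+1)/2.
- **Boundary test.** All current-run trials with intensity in the inclusive
  interval [current intensity, boundary] enter a one-tailed exact binomial
  test against p = 0.5, at α = 0.05/(CWIR_total + 1) where CWIR_total is
  the cumulative sum of all streak weights so far (open streak included).
  On significance the boundary moves to
  `(1 − seenRatio)·boundary + seenRatio·current`, seenRatio being the seen
  fraction of the tested trials (fixed at 0.5 when the subjective measure
  is disabled). The boundary never increases within a run and clamps every
  proposed intensity.
- **Intensity adjustment.** Correct → down one step; incorrect → up one
  step, except that a *seen* incorrect trial leaves the intensity unchanged
  while the subjective exemption is active (before the step size reaches
  its floor). Results are snapped to the intensity grid when one is set
  (ties snap downward, the conservative direction) and clamped to
  [scale minimum, boundary].
- **Step size.** Shrinks by the configured decrement at each reversal
  (correctness flip), floored at the minimum step. A per-trial trigger is
  available; reversal-triggered shrinkage is the default because it is the
  standard transformed-staircase convention and keeps the exemption window
  a meaningful length.
- **Estimate.** θ̂ per run is the weight-averaged mean intensity of the
  incorrect streaks (an open trailing streak is closed for estimation); a
  run with no errors at all falls back to the scale minimum and is flagged.
  The final threshold averages the runs (default two), which are fully
  independent (boundary, step and bookkeeping reset).

Defaults (simulation mode): continuous 0–200 ms scale, steps 32 → 4 by 4,
78 trials × 2 runs. Experiment presets: ISI mode on a 120 Hz frame grid
(quantum 25/3 ms, steps 4 frames → 1 frame, paired-trial updates where the
intensity moves only after both trials of a pair agree); contrast mode on
[0.1, 1] with steps 0.2 → 0.05. In paired mode a both-incorrect pair is
exempt from the increase if either of its trials was rated seen.

Ambiguities resolved here (both configurable): the α divisor uses the
*cumulative* CWIR rather than the current streak (an accumulating quantity
matches the intent of harsher correction near the threshold and is the more
conservative reading for the boundary); boundary-test trials come from the
current run only.

## Baselines

Parameters live in `BaselineConfig`; every method honours the same scale
clamping and runs 156 trials by default (the budget of a full STEP
calibration).

- **Staircase** (1-up 1-down): fixed step 8 by default (optional
  reversal-triggered decrement), estimators: mean of reversal intensities
  (default), last intensity, or second-highest intensity of the final
  batch.
- **PEST**: Wald sequential count at the current level (limit 1.0, target
  0.62); step halves on reversals and doubles after three same-direction
  steps, bounded in [1, 64].
- **QUEST**: gridded posterior over the threshold of a Weibull template
  (assumed θ₂ = 20, λ = 0.02), placement at the posterior-mean threshold's
  target-probability point, estimate = posterior mean. The prior is broad
  and centred mid-scale (mean 100, sd 50): a calibration has no
  participant-specific knowledge, and a prior duplicating the generative
  population would be an oracle. Targeting exactly 0.5 is rejected — every
  sub-threshold intensity performs at 0.5, so the placement rule is
  undefined there.
- **ASA**: Robbins–Monro with Kesten gain, xₙ₊₁ = xₙ − c/(2+m)·(zₙ − φ),
  c = 40, φ = 0.62, m = number of update-direction changes.
- **QUEST+** (optional): joint (θ₁, θ₂) grid posterior with
  expected-entropy-minimising placement; excluded from the default
  benchmark set.

The target probabilities (0.62) are a conventional near-threshold choice
for 2AFC adaptive testing; they were fixed before any benchmarking and not
revisited.

## Evaluation metrics

Over N (estimate θ̂₁ᵢ, truth θ₁ᵢ) pairs:

- RMSE = √(mean (θ̂₁ᵢ − θ₁ᵢ)²), intensity units.
- NRMSE = √(mean ((θ̂₁ᵢ − θ₁ᵢ)/θ₁ᵢ)²); truths of exactly 0 are excluded
  with a logged count (measure-zero under the positive-truncated
  population).
- PRMSE = √(mean (P(θ̂₁ᵢ) − 0.5)²) where P is the participant's *true*
  accuracy curve; every term is ≥ 0 so only overestimation — conscious
  contamination — is penalised, and the metric is bounded by 0.48.

Distribution summaries use type-7 (linear-interpolation) quantiles.
Benchmarks sample the population once and give every method the same
per-participant response-noise seed (paired comparison); all randomness
descends from a single master seed via seed sequences, so reports are
bit-reproducible.

## Benchmark interpretation and known limitations

STEP's estimate is intrinsically conservative. Below θ₁ the staircase is an
unbiased reflected random walk on roughly [0, θ₁ + a small fringe], so
incorrect streaks — and hence θ̂ — average substantially below θ₁
(proportional underestimation of roughly a third, rising with the
shallowness of the subjective curve, since the early seen-exemption blocks
upward moves). On the default synthetic population this yields, at the
1,000-participant scale, RMSE ≈ 12, NRMSE ≈ 0.45, mean signed error ≈ −10,
and PRMSE ≈ 0.006. STEP therefore dominates every baseline on PRMSE — the
metric aligned with its purpose — while the mean-of-reversals staircase and
QUEST, which are nearly unbiased on this *narrow, homogeneous* population
(θ₁ sd 5), post lower RMSE/NRMSE. On heterogeneous populations with a wide
θ₁ range the picture shifts in STEP's favour: reversal-based and
template-based methods degrade with spread and slope mismatch, while STEP's
proportional bias keeps its normalised error roughly constant. The
synthetic population here is deliberately simple (independent parameters,
common scale), so the benchmark shows method *mechanics* under controlled
conditions rather than a verdict about empirical populations.

Numerical choices: exact binomial tail probabilities are computed from
binomial coefficients with caching (no normal approximation); grid
snapping breaks ties downward; QUEST posteriors are renormalised every
update with an underflow guard; estimation with an all-correct run signals
failure rather than inventing a value. The per-participant curve-fitting
utility (`fit_curves`) is a MAP fit under the truncated-normal priors and
deliberately not a hierarchical model — it will not reproduce pooled
empirical fits, only per-observer approximations.

Problem sizes used by the shipped tests: Monte-Carlo checks at 10⁴–1.2×10⁶
trials, boundary type-I control at 10⁴ tests, benchmark at 1,000
participants × 156 trials × 5 methods.
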