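# stepcal

Adaptive calibration of **upper subliminal thresholds** for unconscious-
processing research, built around the Subliminal Threshold Estimation
Procedure (STEP).

## The problem

Masked-priming and related paradigms need, per participant, the *highest*
stimulus intensity (e.g. the prime–mask inter-stimulus interval, ISI, or the
prime contrast) at which objective two-alternative forced-choice (2AFC)
performance is still indistinguishable from chance. Overestimate it and the
"unconscious" effect is contaminated by conscious perception; underestimate
it and real unconscious processing may be missed. Classic adaptive
procedures (staircase, PEST, QUEST, ASA) were designed to locate a point on
the *rising* part of a psychometric curve — not the shoulder where the curve
leaves the chance floor — and rely on reversals, which barely separate
chance from weakly above-chance performance (a reversal occurs with
probability 0.50 at 50% accuracy and 0.48 at 60%).

## The method

Ground truth for a (virtual) observer is a two-part Weibull accuracy curve

    P(x) = 0.5                                          for x ≤ θ₁
    P(x) = 0.5 + (0.5 − λ)(1 − exp(−(x − θ₁)/θ₂))       for x > θ₁

with task threshold θ₁, rise rate θ₂ and lapse rate λ = 0.02 (range
[0.5, 0.98]), plus a logistic visibility curve P(seen) = 1/(1 + e^{(θ−x)/σ})
for the binarised subjective report.

STEP is a 1-up 1-down staircase with three modifications:

1. **Cumulative-weighted incorrect responses (CWIR).** A streak of *k*
   consecutive errors carries weight k(k+1)/2; the run's threshold estimate
   is θ̂ = Σᵢ CWIRᵢ·s̄ᵢ / Σᵢ CWIRᵢ, where s̄ᵢ is the mean intensity during
   streak *i*. Double errors separate chance from 60% accuracy far better
   than reversals (0.25 vs 0.16).
2. **Subjective exemption.** Early in a run (while the step size is above
   its floor), a *seen-but-incorrect* trial does not raise the intensity —
   the error is attributed to a lapse, not to invisibility.
3. **Dynamic upper boundary.** After every trial, the trials whose intensity
   lies between the current intensity and the boundary are tested against
   chance (one-tailed exact binomial test at α = 0.05/(CWIR_total + 1)); a
   significant result pulls the boundary towards the current intensity,
   weighted by the fraction of those trials reported seen.

Two independent 78-trial runs are averaged. The package also provides the
classic baselines (configurable staircase, PEST, QUEST, Kesten-accelerated
stochastic approximation, optional QUEST+), a virtual-participant simulator
(all four curve parameters drawn from positive-truncated normals, mean 25,
sd 5), and a benchmark harness scoring each method by RMSE, NRMSE
(threshold error normalised by the true threshold) and PRMSE (RMS deviation
from chance of *true* accuracy at the estimated threshold — only
overestimation, i.e. conscious contamination, is penalised).

## Worked example

Calibrate a simulated observer (θ₁ = 25, θ₂ = 20, visibility midpoint 25,
spread 10) with STEP:

```bash
$ stepcal calibrate --method step --seed 1
threshold 16.0263 (runs: [22.9275, 9.125])
```

The two runs' CWIR-weighted estimates (22.93 and 9.13 ms) average to a final
ISI of 16.03 ms — below the true 25 ms threshold, i.e. on the safe,
subliminal side.

Benchmark the methods on a shared 200-observer synthetic population with
paired response noise:

```bash
$ stepcal benchmark --methods step,staircase,pest,quest,asa --n 200 --seed 42
      step: RMSE  11.668  NRMSE  0.445  PRMSE 0.0010
 staircase: RMSE   5.957  NRMSE  0.237  PRMSE 0.0402
      pest: RMSE   9.798  NRMSE  0.406  PRMSE 0.1289
     quest: RMSE   4.382  NRMSE  0.194  PRMSE 0.0631
       asa: RMSE  10.389  NRMSE  0.457  PRMSE 0.1504
```

STEP has by far the lowest PRMSE: it almost never lands above the true
threshold, which is exactly what a subliminal calibration must guarantee.
Its RMSE/NRMSE are dominated by a deliberate, conservative underestimation
bias; methods that target a point on the rising curve (PEST, ASA) sit above
threshold and pay for it in PRMSE. See `docs/methods.md` for the error
decomposition and the population model's role in these numbers.

The same machinery drives real experiments through a line protocol
(`stepcal calibrate --method step --interactive` emits `INTENSITY <v>`,
expects `OUTCOME <correct> <seen>`, and finishes with `THRESHOLD <v>`), or
through the library API (`run_step_calibration`, `baseline_calibrate`,
`run_benchmark`).

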