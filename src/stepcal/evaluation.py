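"""Error metrics and the population-scale method benchmark.

Three complementary metrics score a calibration method over a population of
(estimate, truth) pairs:

- RMSE: root mean squared threshold error, in intensity units.
- NRMSE: the same with each error normalised by the true threshold
  (dimensionless; truths of exactly zero are excluded with a logged count).
- PRMSE: RMS deviation from chance of the *true* accuracy evaluated at the
  estimated threshold.  Because accuracy is flat at 0.5 below the true
  threshold, only overestimation is penalised — the metric measures
  conscious contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .baselines import BaselineConfig, baseline_calibrate
from .psychometric import (PopulationSpec, VirtualParticipant, objective_prob,
                           sample_population)
from .step import CalibrationResult, StepConfig, run_step_calibration, \
    simulated_responder

__all__ = [
    "ErrorMetrics",
    "BenchmarkReport",
    "rmse",
    "nrmse",
    "prmse",
    "compute_metrics",
    "run_benchmark",
    "summarize_error_distribution",
]


def _paired(estimates, truths) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {t.shape}")
    if e.size == 0:
        raise ValueError("need at least one (estimate, truth) pair")
    return e, t


def rmse(estimates, truths) -> float:
    """Root mean squared threshold-estimation error."""
    e, t = _paired(estimates, truths)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def nrmse(estimates, truths) -> float:
    """RMSE of errors normalised by the true threshold; truths must be > 0."""
    e, t = _paired(estimates, truths)
    if np.any(t == 0):
        raise ValueError("nrmse undefined at truth = 0; filter such pairs")
    return float(np.sqrt(np.mean(((e - t) / t) ** 2)))


def prmse(estimates, participants: Sequence[VirtualParticipant]) -> float:
    """RMS deviation from chance of true accuracy at the estimated threshold.

    Each term is ``objective_prob(estimate) - 0.5 >= 0``, so underestimation
    contributes nothing and the metric is bounded by 0.48 at the default
    lapse rate.
    """
    e = np.asarray(estimates, dtype=float)
    if len(e) != len(participants):
        raise ValueError("one participant per estimate required")
    dev = np.array([objective_prob(p.objective, max(x, 0.0)) - 0.5
                    for p, x in zip(participants, e)])
    return float(np.sqrt(np.mean(dev ** 2)))


@dataclass(frozen=True)
class ErrorMetrics:
    """The three metrics plus the per-participant error table."""

    rmse: float
    nrmse: float
    prmse: float
    per_participant: pd.DataFrame
    n_excluded_zero_truth: int = 0
    n_failed: int = 0


def compute_metrics(estimates, participants: Sequence[VirtualParticipant],
                    n_failed: int = 0) -> ErrorMetrics:
    """Score a set of threshold estimates against their participants' truth."""
    e = np.asarray(estimates, dtype=float)
    truths = np.array([p.true_threshold for p in participants])
    table = pd.DataFrame({
        "participant": [p.id for p in participants],
        "estimate": e,
        "truth": truths,
        "error": e - truths,
        "normalized_error": np.where(truths > 0, (e - truths) / truths, np.nan),
        "p_at_estimate": [objective_prob(p.objective, max(x, 0.0))
                          for p, x in zip(participants, e)],
    })
    nonzero = truths > 0
    return ErrorMetrics(
        rmse=rmse(e, truths),
        nrmse=nrmse(e[nonzero], truths[nonzero]),
        prmse=prmse(e, participants),
        per_participant=table,
        n_excluded_zero_truth=int(np.sum(~nonzero)),
        n_failed=n_failed,
    )


def summarize_error_distribution(errors, bins: int = 20) -> dict:
    """Median, quartiles (linear-interpolation convention) and histogram."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one error value")
    q1, med, q3 = np.quantile(e, [0.25, 0.5, 0.75])  # type-7 interpolation
    counts, edges = np.histogram(e, bins=bins)
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-method metrics over one shared participant population."""

    metrics: dict[str, ErrorMetrics]
    population_spec: PopulationSpec
    master_seed: int
    summaries: dict[str, dict] = field(default_factory=dict)

    def tidy(self) -> pd.DataFrame:
        frames = []
        for method, m in self.metrics.items():
            f = m.per_participant.copy()
            f.insert(0, "method", method)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "n_participants": self.population_spec.n_participants,
            "methods": {
                name: {
                    "rmse": m.rmse,
                    "nrmse": m.nrmse,
                    "prmse": m.prmse,
                    "n_excluded_zero_truth": m.n_excluded_zero_truth,
                    "n_failed": m.n_failed,
                    "error_summary": self.summaries.get(name, {}),
                }
                for name, m in self.metrics.items()
            },
        }


MethodConfig = StepConfig | BaselineConfig


def _calibrate(config: MethodConfig, responder) -> CalibrationResult:
    if isinstance(config, StepConfig):
        return run_step_calibration(responder, config)
    return baseline_calibrate(responder, config)


def run_benchmark(
    methods: dict[str, MethodConfig],
    population: PopulationSpec | Sequence[VirtualParticipant],
    seed: int = 0,
    progress: Callable[[str, int], None] | None = None,
) -> BenchmarkReport:
    """Run every method on every participant of one shared population.

    The population is sampled once; each participant gets a response-noise
    seed derived deterministically from the master seed, and every method
    replays against the *same* per-participant seed (paired comparison).
    A method failure on a participant is recorded and that participant is
    excluded from the failing method's metrics, with the count reported.
    """
    if not methods:
        raise ValueError("need at least one method")
    if isinstance(population, PopulationSpec):
        spec = population
        participants = sample_population(spec)
    else:
        participants = list(population)
        spec = PopulationSpec(n_participants=len(participants))
    # per-participant child seeds, shared across methods for pairing
    seeds = np.random.SeedSequence(seed).spawn(len(participants))
    metrics: dict[str, ErrorMetrics] = {}
    summaries: dict[str, dict] = {}
    for name, config in methods.items():
        estimates, kept, n_failed = [], [], 0
        for i, participant in enumerate(participants):
            rng = np.random.default_rng(seeds[i])
            responder = simulated_responder(participant, rng)
            try:
                result = _calibrate(config, responder)
            except Exception:
                n_failed += 1
                continue
            estimates.append(result.final_threshold)
            kept.append(participant)
            if progress is not None:
                progress(name, i)
        metrics[name] = compute_metrics(estimates, kept, n_failed=n_failed)
        summaries[name] = summarize_error_distribution(
            metrics[name].per_participant["error"].to_numpy())
    return BenchmarkReport(metrics=metrics, population_spec=spec,
                           master_seed=seed, summaries=summaries)
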