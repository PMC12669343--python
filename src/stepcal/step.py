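"""STEP: adaptive estimation of the upper subliminal threshold.

The controller is a 1-up 1-down staircase with three modifications aimed at
locating the highest intensity at which 2AFC accuracy is still at chance:

1. *Cumulative-weighted incorrect responses (CWIR).*  A streak of ``k``
   consecutive incorrect trials carries weight ``k (k + 1) / 2``; the run's
   threshold estimate is the CWIR-weighted average of the mean intensities of
   those streaks.  Long streaks (strong evidence of chance performance)
   dominate the estimate.
2. *Subjective exemption.*  Early in the run (while the step size is still
   above its floor), an incorrect trial that the observer reported *seeing*
   does not raise the intensity — a seen-but-wrong response is attributed to
   a lapse rather than to invisibility.
3. *Dynamic upper boundary.*  After every trial the trials whose intensity
   lies between the current intensity and the boundary are tested against
   chance with a one-tailed binomial test at ``alpha = alpha_base /
   (CWIR_total + 1)``.  A significant result pulls the boundary towards the
   current intensity, weighted by the fraction of those trials reported seen.

Two independent runs are performed and their thresholds averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Protocol

import numpy as np

from .psychometric import VirtualParticipant, simulate_trial

__all__ = [
    "IntensityScale",
    "StepConfig",
    "TrialRecord",
    "IncorrectSequence",
    "CalibrationState",
    "CalibrationResult",
    "EstimationError",
    "init_run_state",
    "sequence_weight",
    "update_cwir",
    "adjust_intensity",
    "update_step_size",
    "binomial_boundary_test",
    "update_boundary",
    "estimate_run_threshold",
    "run_step_calibration",
    "simulated_responder",
]

Responder = Callable[[float], tuple[bool, bool]]

#: one display frame at 120 Hz, in ms; divides the 0-200 ms ISI range exactly
FRAME_MS = 25.0 / 3.0


@dataclass(frozen=True)
class IntensityScale:
    """Bounded (optionally quantised) stimulus-intensity axis.

    Larger values are always more visible.  ``quantum``, if set, restricts
    intensities to the grid ``minimum + k * quantum`` (e.g. display frames
    for an inter-stimulus interval); off-grid values snap to the nearest
    grid point, ties snapping downward (towards less visible).
    """

    minimum: float
    maximum: float
    quantum: float | None = None

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValueError("scale requires minimum < maximum")
        if self.quantum is not None:
            if self.quantum <= 0:
                raise ValueError("quantum must be > 0")
            span = (self.maximum - self.minimum) / self.quantum
            if abs(span - round(span)) > 1e-9:
                raise ValueError("quantum must divide (maximum - minimum)")

    def snap(self, value: float) -> float:
        if self.quantum is None:
            return value
        steps = (value - self.minimum) / self.quantum
        lo = math.floor(steps)
        frac = steps - lo
        k = lo if frac <= 0.5 + 1e-12 else lo + 1  # tie -> lower grid point
        return self.minimum + k * self.quantum

    def clamp(self, value: float, upper: float | None = None) -> float:
        hi = self.maximum if upper is None else min(upper, self.maximum)
        return min(max(value, self.minimum), hi)


def isi_scale() -> IntensityScale:
    """0-200 ms inter-stimulus interval on a 120 Hz frame grid."""
    return IntensityScale(0.0, 200.0, quantum=FRAME_MS)


def contrast_scale() -> IntensityScale:
    """Prime contrast between 0.1 and 1."""
    return IntensityScale(0.1, 1.0)


@dataclass(frozen=True)
class StepConfig:
    """Full parameterisation of a STEP calibration.

    Defaults are the simulation-mode settings: continuous 0-200 ms scale,
    initial step 32, decrement 4 down to a 4-unit floor, 78 trials per run
    and two runs (156 trials total).
    """

    scale: IntensityScale = field(
        default_factory=lambda: IntensityScale(0.0, 200.0))
    initial_step: float = 32.0
    step_decrement: float = 4.0
    min_step: float = 4.0
    trials_per_run: int = 78
    n_runs: int = 2
    use_subjective: bool = True
    paired_trial_mode: bool = False
    alpha_base: float = 0.05
    step_decrease_trigger: str = "per_reversal"  # or "per_trial"

    def __post_init__(self) -> None:
        if self.min_step > self.initial_step:
            raise ValueError("min_step must be <= initial_step")
        if self.min_step <= 0:
            raise ValueError("min_step must be > 0")
        if self.trials_per_run < 1:
            raise ValueError("trials_per_run must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.alpha_base < 1:
            raise ValueError("alpha_base must lie in (0, 1)")
        if self.step_decrease_trigger not in ("per_reversal", "per_trial"):
            raise ValueError(
                "step_decrease_trigger must be 'per_reversal' or 'per_trial'")

    @staticmethod
    def isi_experiment(**overrides) -> "StepConfig":
        """Experiment settings for the ISI mode: frame-quantised steps
        (32 -> 8 by 8) and paired-trial updates emulating a 4 ms step."""
        defaults = dict(
            scale=isi_scale(), initial_step=4 * FRAME_MS,
            step_decrement=FRAME_MS, min_step=FRAME_MS,
            paired_trial_mode=True,
        )
        defaults.update(overrides)
        return StepConfig(**defaults)

    @staticmethod
    def contrast_experiment(**overrides) -> "StepConfig":
        defaults = dict(
            scale=contrast_scale(), initial_step=0.2, step_decrement=0.05,
            min_step=0.05,
        )
        defaults.update(overrides)
        return StepConfig(**defaults)


@dataclass(frozen=True)
class TrialRecord:
    index: int
    intensity: float
    correct: bool
    seen: bool
    step_size: float
    boundary: float
    cwir_current: int


@dataclass(frozen=True)
class IncorrectSequence:
    """A maximal streak of consecutive incorrect trials."""

    mean_intensity: float
    length: int

    @property
    def weight(self) -> int:
        return sequence_weight(self.length)


@dataclass
class CalibrationState:
    """Mutable per-run state of the STEP controller."""

    config: StepConfig
    current_intensity: float
    current_step: float
    boundary: float
    history: list[TrialRecord] = field(default_factory=list)
    open_sequence: list[float] = field(default_factory=list)
    sequences: list[IncorrectSequence] = field(default_factory=list)
    min_step_reached: bool = False
    last_correct: bool | None = None
    boundary_trajectory: list[float] = field(default_factory=list)

    @property
    def cwir_current(self) -> int:
        """Length of the trailing incorrect streak."""
        return len(self.open_sequence)

    @property
    def cwir_total(self) -> int:
        """Cumulative sum of all sequence weights so far, open streak included."""
        return sum(s.weight for s in self.sequences) + sequence_weight(
            len(self.open_sequence))


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a full calibration (all runs)."""

    run_thresholds: list[float]
    final_threshold: float
    logs: list[list[TrialRecord]]
    boundary_trajectory: list[list[float]]
    method: str = "step"
    flags: list[str] = field(default_factory=list)


class EstimationError(RuntimeError):
    """Raised when a run provides no usable threshold evidence."""


def init_run_state(config: StepConfig) -> CalibrationState:
    """Fresh per-run state: intensity and boundary at the scale maximum."""
    return CalibrationState(
        config=config,
        current_intensity=config.scale.maximum,
        current_step=config.initial_step,
        boundary=config.scale.maximum,
        min_step_reached=config.initial_step <= config.min_step,
    )


def sequence_weight(k: int) -> int:
    """Weight of a streak of ``k`` consecutive incorrect trials: k(k+1)/2."""
    if k < 0:
        raise ValueError("streak length must be >= 0")
    return k * (k + 1) // 2


def update_cwir(state: CalibrationState, correct: bool,
                intensity: float | None = None) -> CalibrationState:
    """Advance the incorrect-streak bookkeeping with one response.

    A correct response closes any open streak into ``state.sequences``
    (recording its mean intensity and triangular weight); an incorrect
    response extends the open streak with the trial's intensity.
    """
    if intensity is None:
        intensity = state.current_intensity
    if correct:
        if state.open_sequence:
            state.sequences.append(IncorrectSequence(
                mean_intensity=float(np.mean(state.open_sequence)),
                length=len(state.open_sequence),
            ))
            state.open_sequence = []
    else:
        state.open_sequence.append(intensity)
    return state


def adjust_intensity(state: CalibrationState, correct: bool,
                     seen: bool) -> CalibrationState:
    """One staircase move: down after correct, up after incorrect.

    A seen-but-incorrect trial leaves the intensity unchanged while the
    subjective exemption is active (``use_subjective`` and the step size has
    not yet hit its floor).  The result is snapped to the grid and clamped
    into ``[scale.minimum, boundary]``.
    """
    cfg = state.config
    x = state.current_intensity
    if correct:
        x -= state.current_step
    elif seen and cfg.use_subjective and not state.min_step_reached:
        pass  # lapse-attributed error: do not raise intensity
    else:
        x += state.current_step
    state.current_intensity = cfg.scale.clamp(cfg.scale.snap(x),
                                              upper=state.boundary)
    return state


def update_step_size(state: CalibrationState,
                     reversal_occurred: bool) -> CalibrationState:
    """Shrink the step when the configured trigger fires, floored at min_step."""
    cfg = state.config
    fires = (reversal_occurred if cfg.step_decrease_trigger == "per_reversal"
             else True)
    if fires and not state.min_step_reached:
        state.current_step = max(state.current_step - cfg.step_decrement,
                                 cfg.min_step)
        if state.current_step <= cfg.min_step:
            state.min_step_reached = True
    return state


@lru_cache(maxsize=65536)
def _binom_upper_tail(successes: int, n: int) -> float:
    """Exact P(X >= successes) for X ~ Binomial(n, 0.5)."""
    return float(sum(math.comb(n, j) for j in range(successes, n + 1))
                 ) * 0.5 ** n


def _select_boundary_trials(state: CalibrationState) -> list[TrialRecord]:
    lo, hi = state.current_intensity, state.boundary
    return [t for t in state.history if lo <= t.intensity <= hi]


def binomial_boundary_test(
    state: CalibrationState,
) -> tuple[float, float, bool]:
    """Test trials between the current intensity and the boundary against chance.

    Returns ``(p_value, alpha, significant)`` where ``p_value`` is the exact
    one-tailed binomial upper-tail probability of the observed number of
    correct responses under p = 0.5, and ``alpha = alpha_base /
    (CWIR_total + 1)``.  With no trials in range the test is skipped
    (``p_value`` is NaN, never significant).
    """
    alpha = state.config.alpha_base / (state.cwir_total + 1)
    selected = _select_boundary_trials(state)
    if not selected:
        return float("nan"), alpha, False
    n = len(selected)
    k = sum(t.correct for t in selected)
    p = _binom_upper_tail(k, n)
    return p, alpha, p < alpha


def update_boundary(state: CalibrationState) -> CalibrationState:
    """Pull the boundary towards the current intensity after a significant test.

    The pull is weighted by the seen ratio of the selected trials
    (``newBoundary = (1 - seenRatio) * boundary + seenRatio * current``);
    without the subjective measure a fixed weight of 0.5 is used.
    """
    selected = _select_boundary_trials(state)
    if not selected:
        return state
    if state.config.use_subjective:
        seen_ratio = sum(t.seen for t in selected) / len(selected)
    else:
        seen_ratio = 0.5
    state.boundary = ((1.0 - seen_ratio) * state.boundary
                      + seen_ratio * state.current_intensity)
    state.current_intensity = min(state.current_intensity, state.boundary)
    return state


def estimate_run_threshold(state: CalibrationState) -> float:
    """CWIR-weighted average of the mean intensities of the incorrect streaks.

    An open trailing streak is included (closed for estimation).  Raises
    :class:`EstimationError` when the run contains no incorrect trial.
    """
    sequences = list(state.sequences)
    if state.open_sequence:
        sequences.append(IncorrectSequence(
            mean_intensity=float(np.mean(state.open_sequence)),
            length=len(state.open_sequence),
        ))
    if not sequences:
        raise EstimationError("run contains no incorrect responses")
    weights = np.array([s.weight for s in sequences], dtype=float)
    means = np.array([s.mean_intensity for s in sequences])
    return float(np.sum(weights * means) / np.sum(weights))


def _run_single(responder: Responder, config: StepConfig
                ) -> tuple[float, list[TrialRecord], list[float], list[str]]:
    state = init_run_state(config)
    flags: list[str] = []
    pending: list[tuple[bool, bool]] = []  # buffered outcomes in paired mode
    for t in range(config.trials_per_run):
        intensity = state.current_intensity
        correct, seen = responder(intensity)
        correct, seen = bool(correct), bool(seen)

        update_cwir(state, correct, intensity)
        reversal = state.last_correct is not None and correct != state.last_correct
        state.last_correct = correct

        state.history.append(TrialRecord(
            index=t, intensity=intensity, correct=correct, seen=seen,
            step_size=state.current_step, boundary=state.boundary,
            cwir_current=state.cwir_current,
        ))

        _, _, significant = binomial_boundary_test(state)
        if significant:
            update_boundary(state)
        state.boundary_trajectory.append(state.boundary)

        if config.paired_trial_mode:
            pending.append((correct, seen))
            if len(pending) == 2:
                (c1, s1), (c2, s2) = pending
                pending = []
                if c1 and c2:
                    adjust_intensity(state, correct=True, seen=False)
                elif not c1 and not c2:
                    # exemption if either trial of the pair was rated seen
                    adjust_intensity(state, correct=False, seen=s1 or s2)
                # mixed pair: intensity unchanged
        else:
            adjust_intensity(state, correct, seen)
        update_step_size(state, reversal)

    try:
        threshold = estimate_run_threshold(state)
    except EstimationError:
        threshold = config.scale.minimum
        flags.append("no_incorrect_responses")
    return threshold, state.history, state.boundary_trajectory, flags


def run_step_calibration(responder: Responder,
                         config: StepConfig | None = None) -> CalibrationResult:
    """Run the full STEP procedure against a trial-outcome source.

    ``responder`` maps a proposed intensity to a ``(correct, seen)`` pair.
    Each of ``config.n_runs`` runs starts from a fresh state (boundary, step
    size and CWIR bookkeeping reset); the final threshold is the arithmetic
    mean of the per-run estimates.
    """
    config = config or StepConfig()
    thresholds, logs, bounds, flags = [], [], [], []
    for _ in range(config.n_runs):
        th, log, traj, fl = _run_single(responder, config)
        thresholds.append(th)
        logs.append(log)
        bounds.append(traj)
        flags.extend(fl)
    return CalibrationResult(
        run_thresholds=thresholds,
        final_threshold=float(np.mean(thresholds)),
        logs=logs,
        boundary_trajectory=bounds,
        method="step",
        flags=flags,
    )


def simulated_responder(participant: VirtualParticipant,
                        rng: np.random.Generator) -> Responder:
    """Responder backed by a virtual participant's ground-truth curves."""

    def respond(intensity: float) -> tuple[bool, bool]:
        return simulate_trial(participant, intensity, rng)

    return respond
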