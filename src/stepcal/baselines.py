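"""Reference calibration procedures for benchmarking against STEP.

Implements the classic adaptive methods a psychophysics lab would reach for:
the 1-up 1-down staircase (fixed or decrementing step, three threshold
estimators), PEST (Wald-test driven step logic with halving/doubling
heuristics), QUEST (gridded Bayesian posterior over the threshold of an
assumed Weibull template), the Kesten-accelerated stochastic approximation
(ASA) and, optionally, a two-parameter QUEST+ variant with expected-entropy
stimulus placement.

All methods honour the same intensity-scale clamping contract as STEP and
report their trial history through the shared :class:`CalibrationResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .psychometric import ObjectiveCurve, objective_prob
from .step import (CalibrationResult, EstimationError, IntensityScale,
                   Responder, TrialRecord)

__all__ = [
    "BaselineConfig",
    "staircase_calibrate",
    "pest_calibrate",
    "quest_calibrate",
    "asa_calibrate",
    "questplus_calibrate",
    "baseline_calibrate",
    "mean_of_reversals",
]

_METHODS = ("staircase", "pest", "quest", "asa", "questplus")
_ESTIMATORS = ("mean_of_reversals", "last_intensity",
               "second_highest_final_batch", "posterior_mean")


@dataclass(frozen=True)
class BaselineConfig:
    """Configuration shared by all baseline methods.

    Method-specific fields are ignored by the other methods.  ``trials``
    defaults to 156 so every baseline spends the same budget as a full
    two-run STEP calibration.
    """

    method: str = "staircase"
    scale: IntensityScale = field(
        default_factory=lambda: IntensityScale(0.0, 200.0))
    trials: int = 156
    threshold_estimator: str | None = None  # default chosen per method

    # staircase
    step_size: float = 8.0
    step_decrement: float = 0.0  # 0 -> fixed-step staircase
    min_step: float = 8.0
    final_batch_size: int = 10

    # PEST
    pest_initial_step: float = 32.0
    pest_min_step: float = 1.0
    pest_max_step: float = 64.0
    pest_wald_limit: float = 1.0
    pest_target: float = 0.62
    pest_double_after: int = 3  # same-direction steps before doubling

    # QUEST / QUEST+ — broad prior centred mid-scale: the calibration starts
    # with no participant-specific knowledge of the threshold
    quest_prior_mean: float = 100.0
    quest_prior_sd: float = 50.0
    quest_target: float = 0.62
    quest_slope: float = 20.0  # assumed theta2 of the Weibull template
    quest_lapse: float = 0.02
    quest_grid_step: float = 0.5

    # ASA
    asa_c: float = 40.0
    asa_target: float = 0.62

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {_METHODS}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        est = self.estimator
        if est not in _ESTIMATORS:
            raise ValueError(f"unknown estimator {est!r}; one of {_ESTIMATORS}")
        for name, p in (("pest_target", self.pest_target),
                        ("asa_target", self.asa_target)):
            if not 0.5 < p < 1.0:
                raise ValueError(f"{name} must lie in (0.5, 1), got {p}")
        if not 0.5 < self.quest_target < 1.0:
            raise ValueError(
                "quest_target must lie in (0.5, 1): targeting chance exactly "
                "gives the assumed template no placement information (every "
                "sub-threshold intensity performs at 0.5)")

    @property
    def estimator(self) -> str:
        if self.threshold_estimator is not None:
            return self.threshold_estimator
        return {"staircase": "mean_of_reversals",
                "pest": "last_intensity",
                "quest": "posterior_mean",
                "questplus": "posterior_mean",
                "asa": "last_intensity"}[self.method]


def _record(index, intensity, correct, seen, step, boundary) -> TrialRecord:
    return TrialRecord(index=index, intensity=float(intensity),
                       correct=bool(correct), seen=bool(seen),
                       step_size=float(step), boundary=float(boundary),
                       cwir_current=0)


def mean_of_reversals(log: list[TrialRecord]) -> float:
    """Average intensity at reversal trials (correctness flips)."""
    reversals = [log[i].intensity for i in range(1, len(log))
                 if log[i].correct != log[i - 1].correct]
    if not reversals:
        raise EstimationError("no reversals in staircase run")
    return float(np.mean(reversals))


def _finalize(log, cfg: BaselineConfig, last_intensity: float,
              posterior_mean: float | None = None) -> tuple[float, list[str]]:
    flags: list[str] = []
    est = cfg.estimator
    if est == "mean_of_reversals":
        try:
            return mean_of_reversals(log), flags
        except EstimationError:
            flags.append("no_reversals")
            return float(last_intensity), flags
    if est == "last_intensity":
        return float(last_intensity), flags
    if est == "second_highest_final_batch":
        batch = sorted(t.intensity for t in log[-cfg.final_batch_size:])
        return float(batch[-2] if len(batch) >= 2 else batch[-1]), flags
    if est == "posterior_mean":
        if posterior_mean is None:
            raise ValueError("posterior_mean estimator needs a posterior")
        return float(posterior_mean), flags
    raise AssertionError(est)


def staircase_calibrate(responder: Responder,
                        config: BaselineConfig) -> CalibrationResult:
    """1-up 1-down staircase with fixed or reversal-decrementing step."""
    scale = config.scale
    x = scale.maximum
    step = config.step_size
    log: list[TrialRecord] = []
    last_correct: bool | None = None
    for t in range(config.trials):
        correct, seen = responder(x)
        log.append(_record(t, x, correct, seen, step, scale.maximum))
        reversal = last_correct is not None and bool(correct) != last_correct
        last_correct = bool(correct)
        x = scale.clamp(scale.snap(x - step if correct else x + step))
        if config.step_decrement > 0 and reversal:
            step = max(step - config.step_decrement, config.min_step)
    threshold, flags = _finalize(log, config, x)
    return CalibrationResult([threshold], threshold, [log],
                             [[scale.maximum] * len(log)],
                             method="staircase", flags=flags)


def pest_calibrate(responder: Responder,
                   config: BaselineConfig) -> CalibrationResult:
    """Parameter Estimation by Sequential Testing.

    Runs a Wald sequential count at the current level: once the number of
    correct responses deviates from ``target * n`` by more than the Wald
    limit, the level moves.  Classic step heuristics: halve the step on each
    reversal, double it after ``pest_double_after`` consecutive steps in the
    same direction.
    """
    scale = config.scale
    x = scale.maximum
    step = config.pest_initial_step
    n_at_level = 0
    correct_at_level = 0
    last_direction = 0
    same_direction_steps = 0
    log: list[TrialRecord] = []
    for t in range(config.trials):
        correct, seen = responder(x)
        log.append(_record(t, x, correct, seen, step, scale.maximum))
        n_at_level += 1
        correct_at_level += int(correct)
        expected = config.pest_target * n_at_level
        deviation = correct_at_level - expected
        direction = 0
        if deviation >= config.pest_wald_limit:
            direction = -1  # too easy -> decrease intensity
        elif deviation <= -config.pest_wald_limit:
            direction = +1  # too hard -> increase intensity
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                step = max(step / 2.0, config.pest_min_step)
                same_direction_steps = 1
            else:
                same_direction_steps += 1
                if same_direction_steps > config.pest_double_after:
                    step = min(step * 2.0, config.pest_max_step)
            x = scale.clamp(scale.snap(x + direction * step))
            last_direction = direction
            n_at_level = 0
            correct_at_level = 0
    threshold, flags = _finalize(log, config, x)
    return CalibrationResult([threshold], threshold, [log],
                             [[scale.maximum] * len(log)],
                             method="pest", flags=flags)


class _QuestPosterior:
    """Gridded posterior over the threshold of a Weibull accuracy template."""

    def __init__(self, cfg: BaselineConfig):
        self.cfg = cfg
        self.grid = np.arange(cfg.scale.minimum,
                              cfg.scale.maximum + cfg.quest_grid_step / 2,
                              cfg.quest_grid_step)
        logp = -0.5 * ((self.grid - cfg.quest_prior_mean)
                       / cfg.quest_prior_sd) ** 2
        self.posterior = np.exp(logp - logp.max())
        self.posterior /= self.posterior.sum()

    def p_correct(self, intensity: float) -> np.ndarray:
        """Template accuracy at ``intensity`` for every candidate threshold."""
        cfg = self.cfg
        above = intensity > self.grid
        rise = 1.0 - np.exp(-(intensity - self.grid) / cfg.quest_slope)
        return np.where(above, 0.5 + (0.5 - cfg.quest_lapse) * rise, 0.5)

    def update(self, intensity: float, correct: bool) -> None:
        like = self.p_correct(intensity) if correct else 1.0 - self.p_correct(
            intensity)
        self.posterior = self.posterior * like
        total = self.posterior.sum()
        if total <= 0:  # underflow guard: fall back to the likelihood shape
            self.posterior = np.clip(like, 1e-300, None)
            total = self.posterior.sum()
        self.posterior /= total

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.posterior))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(np.sum((self.grid - m) ** 2 * self.posterior)))

    def placement(self) -> float:
        """Intensity at which the template at the posterior-mean threshold
        performs at the target probability."""
        cfg = self.cfg
        offset = -cfg.quest_slope * math.log(
            1.0 - (cfg.quest_target - 0.5) / (0.5 - cfg.quest_lapse))
        return self.mean + offset


def quest_calibrate(responder: Responder,
                    config: BaselineConfig) -> CalibrationResult:
    """QUEST: Bayesian threshold tracking under an assumed Weibull template."""
    post = _QuestPosterior(config)
    scale = config.scale
    log: list[TrialRecord] = []
    x = scale.maximum
    for t in range(config.trials):
        x = scale.clamp(scale.snap(post.placement()))
        correct, seen = responder(x)
        log.append(_record(t, x, correct, seen, 0.0, scale.maximum))
        post.update(x, bool(correct))
    threshold, flags = _finalize(log, config, x, posterior_mean=post.mean)
    return CalibrationResult([threshold], threshold, [log],
                             [[scale.maximum] * len(log)],
                             method="quest", flags=flags)


def asa_calibrate(responder: Responder,
                  config: BaselineConfig) -> CalibrationResult:
    """Accelerated stochastic approximation (Robbins-Monro with Kesten gain).

    Update: ``x <- x - (c / (2 + m)) * (z - phi)`` where ``z`` is the binary
    response, ``phi`` the target probability and ``m`` the number of
    reversals (direction changes of the update) so far.
    """
    scale = config.scale
    x = scale.maximum
    m = 0
    last_sign = 0
    log: list[TrialRecord] = []
    for t in range(config.trials):
        correct, seen = responder(x)
        gain = config.asa_c / (2.0 + m)
        log.append(_record(t, x, correct, seen, gain, scale.maximum))
        z = float(bool(correct))
        delta = z - config.asa_target
        sign = int(np.sign(delta))
        if last_sign != 0 and sign != 0 and sign != last_sign:
            m += 1
        if sign != 0:
            last_sign = sign
        x = scale.clamp(scale.snap(x - gain * delta))
    threshold, flags = _finalize(log, config, x)
    return CalibrationResult([threshold], threshold, [log],
                             [[scale.maximum] * len(log)],
                             method="asa", flags=flags)


def questplus_calibrate(responder: Responder,
                        config: BaselineConfig) -> CalibrationResult:
    """Two-parameter QUEST+ (threshold and rise rate) with entropy placement.

    Maintains a joint grid posterior over (theta1, theta2) of the Weibull
    template and places each trial at the candidate intensity minimising the
    expected posterior entropy.  Optional; not part of the default benchmark
    set.
    """
    cfg = config
    scale = cfg.scale
    t1_grid = np.arange(scale.minimum, scale.maximum + 2.0, 4.0)
    t2_grid = np.array([5.0, 10.0, 20.0, 40.0])
    T1, T2 = np.meshgrid(t1_grid, t2_grid, indexing="ij")
    logp = -0.5 * ((T1 - cfg.quest_prior_mean) / cfg.quest_prior_sd) ** 2
    post = np.exp(logp - logp.max())
    post /= post.sum()
    candidates = np.linspace(scale.minimum, scale.maximum, 21)

    def p_correct(x):
        above = x > T1
        rise = 1.0 - np.exp(-np.clip(x - T1, 0, None) / T2)
        return np.where(above, 0.5 + (0.5 - cfg.quest_lapse) * rise, 0.5)

    def entropy(p):
        q = p[p > 0]
        return -np.sum(q * np.log(q))

    log: list[TrialRecord] = []
    for t in range(cfg.trials):
        best_x, best_h = candidates[0], np.inf
        for x in candidates:
            pc = p_correct(x)
            p_resp_correct = float(np.sum(post * pc))
            post_c = post * pc
            post_i = post * (1.0 - pc)
            sc, si = post_c.sum(), post_i.sum()
            h = 0.0
            if sc > 0:
                h += p_resp_correct * entropy(post_c / sc)
            if si > 0:
                h += (1.0 - p_resp_correct) * entropy(post_i / si)
            if h < best_h:
                best_h, best_x = h, x
        x = scale.clamp(scale.snap(best_x))
        correct, seen = responder(x)
        log.append(_record(t, x, correct, seen, 0.0, scale.maximum))
        like = p_correct(x) if correct else 1.0 - p_correct(x)
        post = post * like
        total = post.sum()
        if total <= 0:
            post = np.clip(like, 1e-300, None)
            total = post.sum()
        post /= total
    pmean = float(np.sum(T1 * post))
    threshold, flags = _finalize(log, cfg, log[-1].intensity,
                                 posterior_mean=pmean)
    return CalibrationResult([threshold], threshold, [log],
                             [[scale.maximum] * len(log)],
                             method="questplus", flags=flags)


_DISPATCH = {
    "staircase": staircase_calibrate,
    "pest": pest_calibrate,
    "quest": quest_calibrate,
    "asa": asa_calibrate,
    "questplus": questplus_calibrate,
}


def baseline_calibrate(responder: Responder,
                       config: BaselineConfig) -> CalibrationResult:
    """Dispatch to the configured baseline method."""
    return _DISPATCH[config.method](responder, config)
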