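"""Ground-truth psychometric model and virtual-participant simulation.

The objective (2AFC accuracy) curve is a two-part Weibull: flat at chance
(0.5) up to the upper subliminal threshold ``theta1``, then rising with rate
constant ``theta2`` towards an asymptote of ``1 - lapse - (0.5 - lapse) =
0.5 + (0.5 - lapse)``.  The subjective ("seen") curve is a logistic CDF with
midpoint ``theta`` and spread ``sigma``.  A virtual participant is a pair of
such curves; its true threshold is ``objective.theta1``.

Populations of virtual participants are drawn from truncated normal
distributions constrained to positive values (default mean 25, sd 5 for every
parameter), and trial outcomes are simulated by comparing independent uniform
draws against the two curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ObjectiveCurve",
    "SubjectiveCurve",
    "VirtualParticipant",
    "PopulationSpec",
    "objective_prob",
    "subjective_prob",
    "sample_population",
    "simulate_trial",
    "simulate_trials",
    "fit_curves",
    "population_to_frame",
    "population_from_frame",
]


@dataclass(frozen=True)
class ObjectiveCurve:
    """Two-part Weibull accuracy curve for a 2AFC task.

    Parameters
    ----------
    theta1 : float
        Upper subliminal threshold (intensity units, >= 0).  Accuracy is
        exactly 0.5 for every intensity at or below it.
    theta2 : float
        Rate constant of the rise above threshold (> 0).
    lapse : float
        Lapse rate; caps the asymptote at ``0.5 + (0.5 - lapse)``
        (0.98 at the default 0.02).
    guess : float
        Chance level, fixed at 0.5 for 2AFC.
    """

    theta1: float
    theta2: float
    lapse: float = 0.02
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.theta1 < 0:
            raise ValueError(f"theta1 must be >= 0, got {self.theta1}")
        if self.theta2 <= 0:
            raise ValueError(f"theta2 must be > 0, got {self.theta2}")
        if not 0 <= self.lapse < 0.5:
            raise ValueError(f"lapse must lie in [0, 0.5), got {self.lapse}")

    def __call__(self, intensity):
        return objective_prob(self, intensity)


@dataclass(frozen=True)
class SubjectiveCurve:
    """Logistic visibility curve: P(seen) = 1 / (1 + exp((theta - x) / sigma))."""

    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def __call__(self, intensity):
        return subjective_prob(self, intensity)


@dataclass(frozen=True)
class VirtualParticipant:
    """A simulated observer: objective and subjective ground-truth curves."""

    objective: ObjectiveCurve
    subjective: SubjectiveCurve
    id: str = "vp"

    @property
    def true_threshold(self) -> float:
        return self.objective.theta1


@dataclass(frozen=True)
class PopulationSpec:
    """Generative distribution of a virtual-participant population.

    Each of the four psychometric parameters is drawn independently from a
    normal distribution truncated to positive values.  Defaults follow the
    mildly informative priors used for empirical curve fitting: mean 25,
    sd 5 for every parameter.
    """

    n_participants: int = 10_000
    theta1: tuple[float, float] = (25.0, 5.0)
    theta2: tuple[float, float] = (25.0, 5.0)
    subj_theta: tuple[float, float] = (25.0, 5.0)
    subj_sigma: tuple[float, float] = (25.0, 5.0)
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("theta1", "theta2", "subj_theta", "subj_sigma"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0, got {sd}")
            if mean <= 0 and sd == 0:
                raise ValueError(
                    f"{name}: mean must be > 0 when sd is 0 (positive support)"
                )


def objective_prob(curve: ObjectiveCurve, intensity):
    """Accuracy of the two-part Weibull curve at the given intensity.

    Returns ``guess`` (0.5) for ``intensity <= theta1`` and
    ``0.5 + (0.5 - lapse) * (1 - exp(-(intensity - theta1) / theta2))`` above.
    Accepts scalars or arrays; negative intensities raise ``ValueError``.
    """
    x = np.asarray(intensity, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity must be >= 0")
    above = x > curve.theta1
    rise = 1.0 - np.exp(-(x - curve.theta1) / curve.theta2)
    p = np.where(above, curve.guess + (0.5 - curve.lapse) * rise, curve.guess)
    return float(p) if np.isscalar(intensity) else p


def subjective_prob(curve: SubjectiveCurve, intensity):
    """P(seen) under the logistic visibility curve; scalar or array."""
    x = np.asarray(intensity, dtype=float)
    p = special.expit((x - curve.theta) / curve.sigma)
    return float(p) if np.isscalar(intensity) else p


def _truncated_normal(mean: float, sd: float, size: int, rng: np.random.Generator):
    """Draw from N(mean, sd) truncated to (0, inf)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd  # standardized lower bound
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_population(spec: PopulationSpec) -> list[VirtualParticipant]:
    """Sample a virtual-participant population from truncated normals.

    Deterministic given ``spec.seed``: repeated calls with an equal spec
    yield identical populations.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    t1 = _truncated_normal(*spec.theta1, n, rng)
    t2 = _truncated_normal(*spec.theta2, n, rng)
    st = _truncated_normal(*spec.subj_theta, n, rng)
    ss = _truncated_normal(*spec.subj_sigma, n, rng)
    return [
        VirtualParticipant(
            objective=ObjectiveCurve(theta1=t1[i], theta2=t2[i], lapse=spec.lapse),
            subjective=SubjectiveCurve(theta=st[i], sigma=ss[i]),
            id=f"vp{i:05d}",
        )
        for i in range(n)
    ]


def simulate_trials(
    participant: VirtualParticipant,
    intensities,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (correct, seen) outcomes at each intensity.

    A trial is correct iff a uniform(0, 1) draw falls below the objective
    curve's accuracy at that intensity, and seen iff an independent uniform
    draw falls below the subjective curve's visibility.  Fully reproducible
    given the generator state.
    """
    x = np.atleast_1d(np.asarray(intensities, dtype=float))
    p_correct = objective_prob(participant.objective, x)
    p_seen = subjective_prob(participant.subjective, x)
    correct = rng.random(x.shape) < p_correct
    seen = rng.random(x.shape) < p_seen
    return correct, seen


def simulate_trial(
    participant: VirtualParticipant,
    intensity: float,
    rng: np.random.Generator,
) -> tuple[bool, bool]:
    """Single-trial convenience wrapper around :func:`simulate_trials`."""
    correct, seen = simulate_trials(participant, [intensity], rng)
    return bool(correct[0]), bool(seen[0])


# --- population CSV round-trip -------------------------------------------

_POP_COLUMNS = ["id", "theta1", "theta2", "subj_theta", "subj_sigma"]


def population_to_frame(population: Sequence[VirtualParticipant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in population],
            "theta1": [p.objective.theta1 for p in population],
            "theta2": [p.objective.theta2 for p in population],
            "subj_theta": [p.subjective.theta for p in population],
            "subj_sigma": [p.subjective.sigma for p in population],
        }
    )


def population_from_frame(frame: pd.DataFrame, lapse: float = 0.02
                          ) -> list[VirtualParticipant]:
    missing = [c for c in _POP_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"population table missing columns: {missing}")
    return [
        VirtualParticipant(
            objective=ObjectiveCurve(row.theta1, row.theta2, lapse=lapse),
            subjective=SubjectiveCurve(row.subj_theta, row.subj_sigma),
            id=str(row.id),
        )
        for row in frame.itertuples(index=False)
    ]


# --- optional per-participant MAP curve fitting ---------------------------


def _neg_log_posterior_objective(params, x, k, n, lapse, prior):
    theta1, theta2 = params
    if theta1 < 0 or theta2 <= 0:
        return np.inf
    curve = ObjectiveCurve(theta1, theta2, lapse=lapse)
    p = np.clip(objective_prob(curve, x), 1e-9, 1 - 1e-9)
    ll = np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    (m1, s1), (m2, s2) = prior
    lp = -0.5 * ((theta1 - m1) / s1) ** 2 - 0.5 * ((theta2 - m2) / s2) ** 2
    return -(ll + lp)


def _neg_log_posterior_subjective(params, x, k, n, prior):
    theta, sigma = params
    if sigma <= 0:
        return np.inf
    p = np.clip(subjective_prob(SubjectiveCurve(theta, sigma), x), 1e-9, 1 - 1e-9)
    ll = np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    (m1, s1), (m2, s2) = prior
    lp = -0.5 * ((theta - m1) / s1) ** 2 - 0.5 * ((sigma - m2) / s2) ** 2
    return -(ll + lp)


def fit_curves(
    responses: pd.DataFrame,
    priors: PopulationSpec | None = None,
) -> tuple[ObjectiveCurve, SubjectiveCurve]:
    """Per-participant MAP fit of both psychometric curves.

    ``responses`` needs columns ``intensity``, ``correct`` (0/1) and ``seen``
    (0/1), e.g. a binarised method-of-constant-stimuli table.  Parameters are
    estimated by maximum a posteriori under independent truncated-normal
    priors (default mean 25, sd 5; positive support enforced by the
    optimiser bounds).  With no data the prior mode is returned.  This is a
    single-participant simplification — no pooling across participants.
    """
    spec = priors or PopulationSpec(n_participants=1)
    if len(responses) == 0:
        return (
            ObjectiveCurve(spec.theta1[0], spec.theta2[0], lapse=spec.lapse),
            SubjectiveCurve(spec.subj_theta[0], spec.subj_sigma[0]),
        )
    required = {"intensity", "correct", "seen"}
    if not required.issubset(responses.columns):
        raise ValueError(f"responses must have columns {sorted(required)}")
    grouped = responses.groupby("intensity").agg(
        k_correct=("correct", "sum"),
        k_seen=("seen", "sum"),
        n=("correct", "size"),
    )
    if len(grouped) < 2:
        raise ValueError("fitting needs responses at >= 2 distinct intensities")
    x = grouped.index.to_numpy(dtype=float)
    n = grouped["n"].to_numpy(dtype=float)

    res_o = optimize.minimize(
        _neg_log_posterior_objective,
        x0=[spec.theta1[0], spec.theta2[0]],
        args=(x, grouped["k_correct"].to_numpy(float), n, spec.lapse,
              (spec.theta1, spec.theta2)),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000},
    )
    res_s = optimize.minimize(
        _neg_log_posterior_subjective,
        x0=[spec.subj_theta[0], spec.subj_sigma[0]],
        args=(x, grouped["k_seen"].to_numpy(float), n,
              (spec.subj_theta, spec.subj_sigma)),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000},
    )
    t1, t2 = res_o.x
    th, sg = res_s.x
    return (
        ObjectiveCurve(max(t1, 0.0), max(t2, 1e-6), lapse=spec.lapse),
        SubjectiveCurve(th, max(sg, 1e-6)),
    )
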