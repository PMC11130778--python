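"""Transformed up-down staircase simulating one participant on one assessment.

The engine implements a 3-down-1-up rule: three consecutive correct
responses make the task harder by one step, each error makes it easier.
The rule's stationary point is the stimulus level where the probability
of a correct response is 0.5^(1/3) = 0.794, the usual "approximately 80%
criterion accuracy" of adaptive psychophysics.

A simulated participant is a logistic psychometric function described by
the level at which they respond correctly with exactly that convergence
accuracy (``theta80``), a slope, a guess rate and a lapse rate.  For
adaptive dimensions that span orders of magnitude (exposure durations,
sweep speeds) the staircase steps multiplicatively and the psychometric
function operates on log-level; set-size and similarity dimensions step
additively on a half-unit grid.

A run ends for one of four reasons:

``asymptote``
    performance stabilized — 8 reversals reached, or the SD of the last
    6 reversal levels fell below 5% of the score range;
``ceiling`` / ``floor``
    3 consecutive trials at the best (resp. worst) score bound with
    responses that would push past it;
``trial_cap``
    safety valve (the deployed product had none), flagged on the run.

The score is the mean of the last 6 reversal levels, or the bound value
for bound exits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .errors import EstimationError, ObserverError
from .registry import AssessmentSpec

#: convergence accuracy of the 3-down-1-up rule: p such that p^3 = 1/2.
P_3DOWN1UP = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class ObserverModel:
    """Logistic psychometric observer for one assessment.

    ``theta80`` is expressed in the assessment's adaptive-dimension units
    and is the level at which the observer is correct with probability
    equal to the staircase convergence accuracy (79.4% by default), so a
    well-behaved staircase converges onto ``theta80`` by construction.
    ``slope`` is per unit level for additive dimensions and per log-unit
    for multiplicative ones.
    """

    theta80: float
    slope: float = 1.5
    guess_rate: float = 0.0
    lapse_rate: float = 0.02

    def __post_init__(self):
        if not math.isfinite(self.theta80):
            raise ObserverError("theta80 must be finite")
        if not self.slope > 0:
            raise ObserverError("slope must be positive")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ObserverError("guess_rate must be in [0, 1)")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ObserverError("lapse_rate must be in [0, 0.5)")
        if self.guess_rate + self.lapse_rate >= 1.0:
            raise ObserverError("guess_rate + lapse_rate must be < 1")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    level: float
    correct: bool


@dataclass(frozen=True)
class EngineConfig:
    """Staircase engine settings (the `staircase:` block of a pipeline config)."""

    rule: str = "3down1up"
    accuracy: float = P_3DOWN1UP
    mult_step: float = 1.2          # x / ÷ step for multiplicative dimensions
    add_step_start: float = 1.0     # starting step for additive dimensions
    add_step_min: float = 0.5       # additive step halves per reversal down to this
    reversals_exit: int = 8
    asymptote_sd_frac: float = 0.05
    bound_repeat: int = 3
    trial_cap: int = 120
    estimator_reversals: int = 6
    start_level: float | None = None  # default: midpoint of bounds (geometric for mult dims)

    def __post_init__(self):
        if self.rule != "3down1up":
            raise ObserverError(f"unsupported staircase rule {self.rule!r}")
        if not 0.0 < self.accuracy < 1.0:
            raise ObserverError("accuracy must be in (0, 1)")


@dataclass(frozen=True)
class AssessmentRun:
    participant_id: str
    assessment: str
    trials: tuple[TrialRecord, ...]
    score: float
    exit_reason: str  # asymptote | ceiling | floor | trial_cap
    duration_min: float
    n_reversals: int
    capped: bool = field(default=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def levels(self) -> list[float]:
        return [t.level for t in self.trials]


def psychometric_prob(
    level: float,
    observer: ObserverModel,
    spec: AssessmentSpec,
    accuracy: float = P_3DOWN1UP,
) -> float:
    """Probability of a correct response at ``level``.

    p(x) = γ + (1 − γ − λ) · F(d·s·(x − θ) + c) with F the logistic cdf,
    d = +1 when a numerically larger level makes the task easier (true
    for lower-better dimensions such as exposure duration), and the
    offset c chosen so that p(theta80) equals ``accuracy`` exactly.
    Level and theta are compared on the log scale for multiplicative
    dimensions.
    """
    if not math.isfinite(level):
        raise ObserverError("level must be finite")
    gamma, lam = observer.guess_rate, observer.lapse_rate
    if not (gamma < accuracy < 1.0 - lam):
        raise ObserverError(
            f"convergence accuracy {accuracy:.3f} unreachable with "
            f"guess={gamma}, lapse={lam}"
        )
    if spec.multiplicative:
        if level <= 0 or observer.theta80 <= 0:
            raise ObserverError("multiplicative dimensions require positive levels")
        x, theta = math.log(level), math.log(observer.theta80)
    else:
        x, theta = level, observer.theta80
    d = 1.0 if not spec.higher_better else -1.0  # larger level easier?
    c = logit((accuracy - gamma) / (1.0 - gamma - lam))
    return float(gamma + (1.0 - gamma - lam) * expit(d * observer.slope * (x - theta) + c))


def reversal_levels(levels: list[float]) -> list[float]:
    """Reversal levels of a staircase trajectory.

    A reversal occurs where the direction of level movement flips; its
    level is the local extremum the staircase turned at.  Repeated equal
    levels (e.g. clamped at a bound) do not count as movement.
    """
    moves = []  # (index of level the move departs from, sign)
    for i in range(len(levels) - 1):
        d = levels[i + 1] - levels[i]
        if d != 0:
            moves.append((i, 1 if d > 0 else -1))
    out = []
    for (idx, sign), (_, prev_sign) in zip(moves[1:], moves[:-1]):
        if sign != prev_sign:
            out.append(levels[idx])
    return out


def _default_start(spec: AssessmentSpec) -> float:
    if spec.multiplicative:
        return math.sqrt(spec.score_min * spec.score_max)
    mid = 0.5 * (spec.score_min + spec.score_max)
    return round(mid * 2.0) / 2.0  # half-unit grid


def run_assessment(
    spec: AssessmentSpec,
    observer: ObserverModel,
    rng: np.random.Generator,
    config: EngineConfig = EngineConfig(),
    participant_id: str = "",
) -> AssessmentRun:
    """Simulate one complete adaptive assessment run."""
    harder = spec.direction_sign  # +1: harder means increasing the level
    level = config.start_level if config.start_level is not None else _default_start(spec)
    level = min(max(level, spec.score_min), spec.score_max)
    add_step = config.add_step_start

    trials: list[TrialRecord] = []
    levels: list[float] = []
    streak = 0
    n_rev_seen = 0
    exit_reason = None
    score = math.nan

    for t in range(1, config.trial_cap + 1):
        p = psychometric_prob(level, observer, spec, config.accuracy)
        correct = bool(rng.random() < p)
        trials.append(TrialRecord(t, level, correct))
        levels.append(level)

        # bound exits: `bound_repeat` consecutive trials pinned at a bound
        # with responses that would push past it.
        recent = trials[-config.bound_repeat:]
        if len(recent) == config.bound_repeat:
            if all(tr.level == spec.best_bound and tr.correct for tr in recent):
                exit_reason, score = "ceiling", spec.best_bound
                break
            if all(tr.level == spec.worst_bound and not tr.correct for tr in recent):
                exit_reason, score = "floor", spec.worst_bound
                break

        revs = reversal_levels(levels)
        if len(revs) > n_rev_seen:  # additive step shrinks per reversal
            add_step = max(add_step / 2.0 ** (len(revs) - n_rev_seen), config.add_step_min)
            n_rev_seen = len(revs)
        k = config.estimator_reversals
        if len(revs) >= config.reversals_exit or (
            len(revs) >= k
            and float(np.std(revs[-k:])) < config.asymptote_sd_frac * spec.score_range
        ):
            exit_reason, score = "asymptote", _reversal_mean(revs[-k:], spec)
            break

        # 3-down-1-up level update
        if correct:
            streak += 1
            if streak == 3:
                streak = 0
                level = _step(level, spec, config, add_step, direction=harder)
        else:
            streak = 0
            level = _step(level, spec, config, add_step, direction=-harder)

    capped = exit_reason is None
    if capped:
        exit_reason = "trial_cap"
        revs = reversal_levels(levels)
        score = _reversal_mean(revs, spec) if revs else levels[-1]

    return AssessmentRun(
        participant_id=participant_id,
        assessment=spec.name,
        trials=tuple(trials),
        score=score,
        exit_reason=exit_reason,
        duration_min=len(trials) * spec.trial_seconds / 60.0,
        n_reversals=len(reversal_levels(levels)),
        capped=capped,
    )


def _reversal_mean(revs, spec: AssessmentSpec) -> float:
    """Average reversal levels on the staircase's working scale.

    Multiplicative staircases operate on log-level, so their reversal
    levels are averaged geometrically (the standard transformed up-down
    estimator); additive staircases average arithmetically.
    """
    if spec.multiplicative:
        return float(np.exp(np.mean(np.log(revs))))
    return float(np.mean(revs))


def _step(level, spec, config, add_step, direction):
    """Move one staircase step; direction +1 increases the level."""
    if spec.multiplicative:
        new = level * config.mult_step if direction > 0 else level / config.mult_step
    else:
        new = level + direction * add_step
    return min(max(new, spec.score_min), spec.score_max)


def estimate_score(
    run: AssessmentRun, k: int | None = None, spec: AssessmentSpec | None = None
) -> float:
    """Recompute a run's score from its stored trial sequence.

    Deterministic and idempotent: for any run produced by
    :func:`run_assessment` this equals ``run.score``.  ``k`` is the
    number of trailing reversal levels averaged (engine convention when
    omitted: 6 for asymptote exits, all reversals for capped runs, the
    bound value for bound exits).  ``spec`` defaults to the packaged
    registry entry for ``run.assessment``; pass it explicitly for custom
    assessments.
    """
    if spec is None:
        from .registry import get_spec
        spec = get_spec(run.assessment)
    if run.exit_reason in ("ceiling", "floor"):
        return run.trials[-1].level
    revs = reversal_levels(run.levels)
    if not revs:
        if run.exit_reason == "trial_cap":
            return run.trials[-1].level
        raise EstimationError("run has no reversals and no bound exit")
    if k is None:
        k = len(revs) if run.exit_reason == "trial_cap" else 6
    return _reversal_mean(revs[-k:], spec)
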