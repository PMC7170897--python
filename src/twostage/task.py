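"""Generative model of the two-stage decision task.

A first-stage choice between two options (fractals, coded 0/1) leads to one of
two second-stage states (left = 0, right = 1) that pays a drifting reward.
Two transition regimes are supported:

* **stochastic** — each option commonly maps to one state with probability
  ``p_common`` (0.5 < p <= 1); the mapping is reversed for the other option.
* **deterministic** — the second-stage state stays or switches relative to the
  previous trial according to a pattern over the last three first-stage
  choices (four history classes: SSS, ALT, S1, D12).

Rewards for each state follow independent Gaussian random walks with means
bounded in [0, 100] and additive Gaussian observation noise, the schedule
regime that makes learning rates below 1 optimal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "HISTORY_CLASSES",
    "RewardWalkParams",
    "RewardSchedule",
    "PatternTable",
    "BUILTIN_PATTERNS",
    "TransitionSpec",
    "TaskConfig",
    "TrialRecord",
    "TwoStageEnv",
    "generate_reward_schedule",
    "stochastic_next_state",
    "classify_history",
    "pattern_next_state",
    "env_step",
]

#: History classes over the choice triple (a_t, a_{t-1}, a_{t-2}), current first.
HISTORY_CLASSES = ("SSS", "ALT", "S1", "D12")

STATE_LEFT = 0
STATE_RIGHT = 1


class WrongConditionError(ValueError):
    """A transition rule was invoked under the wrong task condition."""


class PatternConfigError(ValueError):
    """A pattern table is malformed or misses a history class."""


@dataclass(frozen=True)
class RewardWalkParams:
    """Parameters of the bounded Gaussian random-walk reward schedule.

    Units are reward points. Means drift with ``drift_sd`` per trial, realized
    payoffs add noise with ``noise_sd``; both means and payoffs are kept
    inside ``[lower_bound, upper_bound]`` (clip by default, reflect optional).
    """

    lower_bound: float = 0.0
    upper_bound: float = 100.0
    drift_sd: float = 20.0
    noise_sd: float = 20.0
    boundary: str = "clip"  # or "reflect"

    def __post_init__(self) -> None:
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if self.boundary not in ("clip", "reflect"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")


@dataclass(frozen=True)
class RewardSchedule:
    """Per-trial reward means and realized rewards for the two states.

    ``means[t, s]`` and ``rewards[t, s]`` index trial ``t`` and state ``s``
    (0 = left, 1 = right).
    """

    means: np.ndarray
    rewards: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.means.shape[0]


def _bound(x: np.ndarray, lo: float, hi: float, rule: str) -> np.ndarray:
    if rule == "clip":
        return np.clip(x, lo, hi)
    # Reflect about whichever bound was crossed; repeat until inside
    # (a single drift step can overshoot a narrow interval several times).
    span = hi - lo
    y = np.mod(np.asarray(x, dtype=float) - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def generate_reward_schedule(
    n_trials: int,
    params: RewardWalkParams = RewardWalkParams(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    init_means: Optional[Sequence[float]] = None,
) -> RewardSchedule:
    """Draw independent bounded reward walks for the two second-stage states.

    Each state's mean takes a Gaussian step of sd ``drift_sd`` per trial and
    is bounded back into range; the realized reward adds Gaussian noise of sd
    ``noise_sd`` and is bounded the same way. ``init_means`` defaults to
    independent uniform draws on the bounds. Identical ``seed`` (or ``rng``
    state) gives identical output.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = params.lower_bound, params.upper_bound
    if init_means is None:
        start = rng.uniform(lo, hi, size=2)
    else:
        start = np.asarray(init_means, dtype=float)
        if start.shape != (2,):
            raise ValueError("init_means must hold one value per state")
    means = np.empty((n_trials, 2))
    current = start.copy()
    for t in range(n_trials):
        current = _bound(
            current + rng.normal(0.0, params.drift_sd, size=2), lo, hi, params.boundary
        )
        means[t] = current
    rewards = _bound(
        means + rng.normal(0.0, params.noise_sd, size=(n_trials, 2)),
        lo,
        hi,
        params.boundary,
    )
    return RewardSchedule(means=means, rewards=rewards)


@dataclass(frozen=True)
class PatternTable:
    """Deterministic transition pattern over the four choice-history classes.

    ``dialect='stay_switch'`` maps each history class to ``'stay'`` (same
    second-stage state as the previous trial) or ``'switch'``.
    ``dialect='absolute_state'`` maps each class directly to a state id
    (0 = left/B, 1 = right/C), an attractor-style rule.
    """

    outcome: Mapping[str, object]
    pattern_id: object = "custom"
    dialect: str = "stay_switch"

    def __post_init__(self) -> None:
        missing = [h for h in HISTORY_CLASSES if h not in self.outcome]
        if missing:
            raise PatternConfigError(f"pattern misses history classes: {missing}")
        for h in HISTORY_CLASSES:
            o = self.outcome[h]
            if self.dialect == "stay_switch" and o not in ("stay", "switch"):
                raise PatternConfigError(f"bad stay/switch outcome {o!r} for {h}")
            if self.dialect == "absolute_state" and o not in (0, 1):
                raise PatternConfigError(f"bad state outcome {o!r} for {h}")
        if self.dialect not in ("stay_switch", "absolute_state"):
            raise PatternConfigError(f"unknown dialect {self.dialect!r}")


# Built-in patterns 1-4, ordered hardest to easiest. Pattern 4 implements the
# attractor rule "repeat the same first-stage option -> fractal B (left);
# constant alternation -> fractal C (right)", which requires the absolute
# dialect. Patterns 1-3 are synthetic stand-ins: non-trivial stay/switch
# tables chosen once (the experiment's exact tables are not published in the
# main text); replace via a custom PatternTable if the true tables are known.
BUILTIN_PATTERNS: Mapping[int, PatternTable] = {
    1: PatternTable(
        {"SSS": "switch", "ALT": "switch", "S1": "switch", "D12": "stay"}, 1
    ),
    2: PatternTable(
        {"SSS": "switch", "ALT": "switch", "S1": "stay", "D12": "stay"}, 2
    ),
    3: PatternTable(
        {"SSS": "switch", "ALT": "stay", "S1": "switch", "D12": "switch"}, 3
    ),
    4: PatternTable(
        {"SSS": STATE_LEFT, "ALT": STATE_RIGHT, "S1": STATE_LEFT, "D12": STATE_RIGHT},
        4,
        dialect="absolute_state",
    ),
}


@dataclass(frozen=True)
class TransitionSpec:
    """Transition structure of a block: stochastic probabilities or a pattern.

    For the stochastic condition ``common_map[o]`` is the state option ``o``
    reaches with probability ``p_common``; the two options map to opposite
    states (probabilities reversed). For the deterministic condition
    ``pattern`` holds the stay/switch (or absolute) rule.
    """

    condition: str
    p_common: Optional[float] = None
    common_map: Optional[tuple] = None
    pattern: Optional[PatternTable] = None

    def __post_init__(self) -> None:
        if self.condition == "stochastic":
            if self.p_common is None or self.common_map is None:
                raise ValueError("stochastic spec needs p_common and common_map")
            if self.pattern is not None:
                raise ValueError("stochastic spec cannot carry a pattern")
            if not 0.5 < self.p_common <= 1.0:
                raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
            cm = tuple(self.common_map)
            if sorted(cm) != [0, 1]:
                raise ValueError("common_map must map the options to opposite states")
            object.__setattr__(self, "common_map", cm)
        elif self.condition == "deterministic":
            if self.pattern is None:
                raise ValueError("deterministic spec needs a pattern")
            if self.p_common is not None or self.common_map is not None:
                raise ValueError("deterministic spec cannot carry p_common/common_map")
        else:
            raise ValueError(f"unknown condition {self.condition!r}")

    @classmethod
    def stochastic(cls, p_common: float, common_map: tuple = (0, 1)) -> "TransitionSpec":
        return cls("stochastic", p_common=p_common, common_map=common_map)

    @classmethod
    def deterministic(cls, pattern) -> "TransitionSpec":
        if isinstance(pattern, int):
            pattern = BUILTIN_PATTERNS[pattern]
        return cls("deterministic", pattern=pattern)

    @property
    def param(self) -> float:
        """The scalar block parameter: p_common or the pattern id."""
        if self.condition == "stochastic":
            return self.p_common
        pid = self.pattern.pattern_id
        return float(pid) if isinstance(pid, (int, float)) else float("nan")


def stochastic_next_state(
    choice: int, spec: TransitionSpec, rng: np.random.Generator
) -> tuple:
    """Sample the next second-stage state under a stochastic spec.

    Returns ``(state, is_common)`` where ``is_common`` marks whether the
    high-probability mapping fired.
    """
    if spec.condition != "stochastic":
        raise WrongConditionError("stochastic_next_state needs a stochastic spec")
    common = spec.common_map[choice]
    is_common = bool(rng.random() < spec.p_common)
    return (common if is_common else 1 - common), is_common


def classify_history(a_t: int, a_tm1: int, a_tm2: int) -> str:
    """Classify the choice triple (current, one back, two back).

    SSS: all three equal; ALT: alternating (a_t = a_{t-2} != a_{t-1});
    S1: repeat of one back only; D12: current differs, the two lags agree.
    The four classes partition all eight binary triples.
    """
    if a_t == a_tm1:
        return "SSS" if a_tm1 == a_tm2 else "S1"
    return "D12" if a_tm1 == a_tm2 else "ALT"


def pattern_next_state(history: str, prev_state: int, pattern: PatternTable) -> int:
    """Apply a pattern rule: the second-stage state stays or switches.

    Under the absolute dialect the mapped state is returned directly and
    ``prev_state`` is ignored.
    """
    try:
        outcome = pattern.outcome[history]
    except KeyError:
        raise PatternConfigError(f"history class {history!r} not mapped") from None
    if pattern.dialect == "absolute_state":
        return int(outcome)
    if outcome == "stay":
        return int(prev_state)
    return 1 - int(prev_state)


@dataclass(frozen=True)
class TaskConfig:
    """Generative specification of one block."""

    spec: TransitionSpec
    n_trials: int = 100
    walk: RewardWalkParams = field(default_factory=RewardWalkParams)
    screen_width_px: int = 1920
    line_frac: float = 0.7
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.line_frac < 1:
            raise ValueError("line_frac must be in (0, 1)")


@dataclass
class TrialRecord:
    """One observed or simulated trial."""

    trial: int
    choice: int
    state: int
    is_common: Optional[bool]
    reward: float
    reward_left: float
    reward_right: float
    crossing_x: Optional[float] = None
    stay: Optional[bool] = None


class TwoStageEnv:
    """Closed-loop block environment: call :meth:`step` with each choice.

    The reward schedule is drawn up-front from the block seed; the transition
    regime follows ``config.spec``. In deterministic blocks the first two
    trials (no full three-choice history yet) and the initial previous state
    are drawn uniformly at random — the warm-up rule.
    """

    def __init__(self, config: TaskConfig, seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed if seed is None else seed)
        self.rng = rng
        self.schedule = generate_reward_schedule(config.n_trials, config.walk, rng=rng)
        self.t = 0
        self.prev_state: Optional[int] = None
        self.prev_choice: Optional[int] = None
        self.action_history: list = []  # most recent first, length <= 3

    def predicted_state(self, choice: int) -> Optional[int]:
        """The state this choice would reach, if uniquely defined.

        Stochastic blocks: the common-transition state. Deterministic blocks:
        the pattern's prediction, or None during warm-up.
        """
        spec = self.config.spec
        if spec.condition == "stochastic":
            return spec.common_map[choice]
        if len(self.action_history) < 2 or self.prev_state is None:
            return None
        h = classify_history(choice, self.action_history[0], self.action_history[1])
        return pattern_next_state(h, self.prev_state, spec.pattern)

    def step(self, choice: int) -> TrialRecord:
        if self.t >= self.config.n_trials:
            raise IndexError("block exhausted: no trials left in the schedule")
        if choice not in (0, 1):
            raise ValueError(f"choice must be 0 or 1, got {choice!r}")
        spec = self.config.spec
        if spec.condition == "stochastic":
            state, is_common = stochastic_next_state(choice, spec, self.rng)
        else:
            predicted = self.predicted_state(choice)
            if predicted is None:
                state = int(self.rng.integers(2))
            else:
                state = predicted
            is_common = None
        r_left, r_right = self.schedule.rewards[self.t]
        record = TrialRecord(
            trial=self.t,
            choice=choice,
            state=state,
            is_common=is_common,
            reward=float(self.schedule.rewards[self.t, state]),
            reward_left=float(r_left),
            reward_right=float(r_right),
            stay=None if self.prev_choice is None else choice == self.prev_choice,
        )
        self.t += 1
        self.prev_state = state
        self.prev_choice = choice
        self.action_history = [choice] + self.action_history[:2]
        return record


def env_step(env: TwoStageEnv, choice: int):
    """Functional wrapper over :meth:`TwoStageEnv.step`; mutates and returns env."""
    record = env.step(choice)
    return record, env
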