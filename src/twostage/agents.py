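"""Hybrid model-free/model-based reinforcement-learning agents.

The agent caches Rescorla-Wagner values ``v`` for the two second-stage states
and model-free Q-values ``q_mf`` for the two first-stage options, combines
``q_mf`` with a model-based value ``q_mb`` derived from the true transition
structure as a convex mixture with weight ``w``, and chooses via a logistic
rule with sensitivity ``beta`` (optionally plus a perseverance bonus ``rho``
on the previous choice).

Variants differ only in the model-free first-stage target: TD(1) regresses
``q_mf`` toward the obtained reward, TD(0) toward the cached value of the
reached state, TD(lambda) toward their ``lam``-mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .task import TaskConfig, TransitionSpec, TrialRecord, TwoStageEnv
from . import beliefs as _beliefs

__all__ = [
    "AgentParams",
    "AgentValues",
    "VARIANTS",
    "update_second_stage",
    "update_first_stage_mf",
    "model_based_q",
    "hybrid_q",
    "choice_probability",
    "simulate_block",
]

#: Free parameters per fitted model variant, in optimizer order.
VARIANTS = {
    "td1_hybrid": ("alpha", "beta", "w"),
    "td0_hybrid": ("alpha", "beta", "w"),
    "tdlam_hybrid": ("alpha", "beta", "w", "lam"),
    "td1_persev": ("alpha", "beta", "w", "rho"),
    "tdlam_persev": ("alpha", "beta", "w", "lam", "rho"),
}


@dataclass(frozen=True)
class AgentParams:
    """Agent parameters: learning rate, choice sensitivity, model-based weight.

    ``beta`` acts multiplicatively on the Q-value difference inside the
    logistic choice rule (an inverse-temperature role; on the 0-100 point
    scale typical fitted values are ~0.1). ``rho`` is a perseverance bonus in
    logit units on a +/-1 previous-choice indicator; ``lam`` the eligibility
    mixing of the TD(lambda) first-stage target (1 = TD(1)).
    """

    alpha: float
    beta: float
    w: float
    rho: float = 0.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")

    def replace(self, **kw) -> "AgentParams":
        return replace(self, **kw)


@dataclass
class AgentValues:
    """Cached values: ``v[s]`` per second-stage state, ``q_mf[o]`` per option."""

    v: np.ndarray
    q_mf: np.ndarray

    @classmethod
    def initial(cls, value: float = 50.0) -> "AgentValues":
        # midpoint of the 0-100 reward range: unbiased start
        return cls(v=np.full(2, float(value)), q_mf=np.full(2, float(value)))


def update_second_stage(v: float, r: float, alpha: float) -> float:
    """Rescorla-Wagner update of the reached state's value: v + alpha*(r - v)."""
    return v + alpha * (r - v)


def _mf_target(variant: str, r: float, v_reached: float, lam: float) -> float:
    if variant.startswith("td1"):
        return r
    if variant.startswith("td0"):
        return v_reached
    if variant.startswith("tdlam"):
        return lam * r + (1.0 - lam) * v_reached
    raise ValueError(f"unknown variant {variant!r}")


def update_first_stage_mf(
    q: float,
    r: float,
    alpha: float,
    variant: str = "td1_hybrid",
    v_reached: Optional[float] = None,
    lam: float = 1.0,
) -> float:
    """Update the chosen option's model-free Q-value.

    TD(1): toward the reward, ``(1-alpha)*q + alpha*r``. TD(0): toward the
    cached value of the reached state (before that value's own update this
    trial). TD(lambda): toward ``lam*r + (1-lam)*v_reached``.
    """
    if not variant.startswith("td1") and v_reached is None:
        raise ValueError(f"variant {variant!r} needs v_reached")
    target = _mf_target(variant, r, v_reached if v_reached is not None else r, lam)
    return q + alpha * (target - q)


def model_based_q(
    spec: TransitionSpec,
    values: AgentValues,
    predicted_states=(None, None),
) -> np.ndarray:
    """Model-based Q-value of each first-stage option under the true structure.

    Stochastic: the expectation ``p_common*v[common] + (1-p_common)*v[other]``
    per option. Deterministic: the cached value of the uniquely predicted
    state per option (``predicted_states``, from the pattern); options whose
    prediction is undefined (warm-up) fall back to the unweighted mean of v.
    """
    v = values.v
    if spec.condition == "stochastic":
        p = spec.p_common
        out = np.empty(2)
        for o in (0, 1):
            c = spec.common_map[o]
            out[o] = p * v[c] + (1.0 - p) * v[1 - c]
        return out
    fallback = 0.5 * (v[0] + v[1])
    return np.array(
        [fallback if s is None else v[int(s)] for s in predicted_states]
    )


def hybrid_q(q_mb, q_mf, w: float):
    """Convex mixture w*q_mb + (1-w)*q_mf."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must be in [0, 1], got {w}")
    return w * np.asarray(q_mb) + (1.0 - w) * np.asarray(q_mf)


def choice_probability(
    q_hyb,
    beta: float,
    prev_choice: Optional[int] = None,
    rho: float = 0.0,
) -> float:
    """Probability of choosing option 1 under the logistic rule.

    ``P(1) = logistic(beta*(q1 - q0) + rho*ind)`` with ``ind = +1`` if option
    1 was chosen on the previous trial, ``-1`` if option 0, ``0`` if none.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    ind = 0.0 if prev_choice is None else (1.0 if prev_choice == 1 else -1.0)
    z = beta * (q_hyb[1] - q_hyb[0]) + rho * ind
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def simulate_block(
    params: AgentParams,
    config: TaskConfig,
    seed: Optional[int] = None,
    variant: str = "td1_hybrid",
    mouse: Optional["_beliefs.MouseParams"] = None,
    init_value: float = 50.0,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Simulate one closed-loop block; returns the list of TrialRecords.

    If ``mouse`` is given, each trial also gets a cursor line-crossing
    x-coordinate generated from a Bayesian ideal observer's belief about the
    upcoming state given the chosen option (Beta-Bernoulli posterior in the
    stochastic condition; the pattern's prediction, 0.5 during warm-up, in
    the deterministic condition) — independent of the agent's ``w``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    env = TwoStageEnv(config, rng=rng)
    spec = config.spec
    values = AgentValues.initial(init_value)
    belief = _beliefs.BeliefState() if mouse is not None else None
    prev_choice: Optional[int] = None
    records = []
    for _ in range(config.n_trials):
        if spec.condition == "stochastic":
            q_mb = model_based_q(spec, values)
        else:
            preds = (env.predicted_state(0), env.predicted_state(1))
            q_mb = model_based_q(spec, values, predicted_states=preds)
        q = hybrid_q(q_mb, values.q_mf, params.w)
        p1 = choice_probability(q, params.beta, prev_choice, params.rho)
        choice = int(rng.random() < p1)
        if mouse is not None:
            if spec.condition == "stochastic":
                b_right = belief.posterior_right(choice)
            else:
                pred = env.predicted_state(choice)
                b_right = 0.5 if pred is None else float(pred)
            crossing = _beliefs.generate_crossing_x(b_right, mouse, rng)
        record = env.step(choice)
        if mouse is not None:
            record.crossing_x = crossing
            if spec.condition == "stochastic":
                belief.update(choice, record.state)
        r = record.reward
        v_reached = values.v[record.state]
        values.v[record.state] = update_second_stage(v_reached, r, params.alpha)
        values.q_mf[choice] = update_first_stage_mf(
            values.q_mf[choice], r, params.alpha, variant, v_reached, params.lam
        )
        prev_choice = choice
        records.append(record)
    return records
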