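"""Bayesian ideal-observer beliefs and the belief-to-cursor generative map.

The observer tracks, independently for each first-stage option, a
Beta-Bernoulli posterior over which second-stage state the option leads to.
The posterior mean belief that the *right-hand* state is coming drives a
synthetic mouse cursor: the x-coordinate where the cursor crosses the
invisible line (70% of the way down the screen) is linear in the belief's
departure from 0.5 plus Gaussian noise, stored relative to the screen
midline (positive = right).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BeliefState",
    "MouseParams",
    "update_belief",
    "posterior_right",
    "generate_crossing_x",
    "signed_toward_correct",
    "append_beliefs",
]


class BeliefState:
    """Per-option Beta pseudo-counts over the second-stage state identity.

    ``counts[o] = (a, b)``: ``a`` counts observations of the right-hand state
    (state 1) after choosing option ``o``, ``b`` of the left-hand state,
    both including the Beta(a0, b0) prior. By default the two options are
    tracked independently with a flat Beta(1, 1) prior; ``coupled=True``
    mirrors every observation onto the other option's opposite state
    (for observers told the two mappings are reversed).
    """

    def __init__(self, prior=(1.0, 1.0), coupled: bool = False):
        a0, b0 = float(prior[0]), float(prior[1])
        if a0 <= 0 or b0 <= 0:
            raise ValueError("prior pseudo-counts must be positive")
        self.prior = (a0, b0)
        self.coupled = coupled
        self.counts = np.array([[a0, b0], [a0, b0]], dtype=float)

    def copy(self) -> "BeliefState":
        out = BeliefState(self.prior, self.coupled)
        out.counts = self.counts.copy()
        return out

    def update(self, action: int, state: int) -> "BeliefState":
        """Record one observed (action -> state) transition in place."""
        if action not in (0, 1) or state not in (0, 1):
            raise ValueError("action and state must be 0 or 1")
        self.counts[action, 0 if state == 1 else 1] += 1.0
        if self.coupled:
            self.counts[1 - action, 1 if state == 1 else 0] += 1.0
        return self

    def posterior_right(self, action: int) -> float:
        """Posterior mean P(right-hand state | action): a / (a + b)."""
        a, b = self.counts[action]
        return a / (a + b)


def update_belief(belief: BeliefState, action: int, state: int) -> BeliefState:
    """Pure-functional update: returns a new BeliefState, input untouched."""
    return belief.copy().update(action, state)


def posterior_right(belief: BeliefState, action: int) -> float:
    return belief.posterior_right(action)


@dataclass(frozen=True)
class MouseParams:
    """Generative parameters of the cursor line-crossing model.

    ``gain`` is pixels of rightward displacement per unit of belief above
    0.5 (default 500 px: a belief of 0.9 crosses ~200 px right of midline);
    ``noise_sd`` is additive Gaussian trial noise in pixels. Geometry only
    matters for rendering: crossings are stored midline-relative.
    """

    gain: float = 500.0
    noise_sd: float = 50.0
    screen_width: int = 1920
    line_frac: float = 0.7

    def __post_init__(self) -> None:
        if self.gain < 0 or self.noise_sd < 0:
            raise ValueError("gain and noise_sd must be >= 0")
        if not 0 < self.line_frac < 1:
            raise ValueError("line_frac must be in (0, 1)")


def generate_crossing_x(
    belief_right: float,
    params: MouseParams,
    rng: np.random.Generator,
) -> float:
    """Draw the x-coordinate where the cursor crosses the invisible line.

    ``x = gain * (belief_right - 0.5) + N(0, noise_sd)``, midline-relative
    (positive = right). Noise can push the crossing onto the "wrong" side, as
    in real trajectories.
    """
    if not 0.0 <= belief_right <= 1.0:
        raise ValueError("belief_right must be in [0, 1]")
    x = params.gain * (belief_right - 0.5)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd)
    return float(x)


def signed_toward_correct(crossing_x: float, correct_side: int) -> float:
    """Signed distance toward the correct state side.

    Positive if the crossing lies on the side of ``correct_side``
    (0 = left, 1 = right), negative otherwise; magnitude is the pixel
    distance from the midline.
    """
    if correct_side not in (0, 1):
        raise ValueError("correct_side must be 0 (left) or 1 (right)")
    return float(crossing_x if correct_side == 1 else -crossing_x)


def append_beliefs(
    trials: pd.DataFrame,
    prior=(1.0, 1.0),
    group_cols=("subject_id", "block_id"),
) -> pd.DataFrame:
    """Add a ``belief_right`` column: the Beta-Bernoulli posterior mean
    probability of the right-hand state given the trial's chosen option,
    computed from the observations *before* that trial, per block.
    """
    trials = trials.copy()
    a0, b0 = float(prior[0]), float(prior[1])

    def _one_block(g: pd.DataFrame) -> pd.Series:
        choice = g["choice"].to_numpy(int)
        state = g["state"].to_numpy(int)
        n = len(g)
        counts = np.array([[a0, b0], [a0, b0]])
        out = np.empty(n)
        for t in range(n):
            a, b = counts[choice[t]]
            out[t] = a / (a + b)
            counts[choice[t], 0 if state[t] == 1 else 1] += 1.0
        return pd.Series(out, index=g.index)

    cols = [c for c in group_cols if c in trials.columns]
    belief = pd.Series(np.nan, index=trials.index, dtype=float)
    if cols:
        for _, g in trials.groupby(cols, sort=False):
            belief.loc[g.index] = _one_block(g)
    else:
        belief = _one_block(trials)
    trials["belief_right"] = belief
    return trials
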