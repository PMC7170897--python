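"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pandas as pd
import pytest

from twostage import AgentParams, TaskConfig, TransitionSpec, simulate_block
from twostage.cohort import records_to_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_subject_frame(params, configs, seed, subject_id=0, mouse=None,
                       variant="td1_hybrid"):
    """Simulate one agent over a list of block configs, as one trial table."""
    frames = []
    for b, cfg in enumerate(configs):
        recs = simulate_block(params, cfg, seed=seed + 1000 * b, mouse=mouse,
                              variant=variant)
        frames.append(records_to_frame(recs, subject_id, b, cfg))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def stochastic_block():
    cfg = TaskConfig(TransitionSpec.stochastic(0.8), n_trials=100)
    recs = simulate_block(AgentParams(0.7, 0.1, 0.6), cfg, seed=7)
    return records_to_frame(recs, 0, 0, cfg)


@pytest.fixture
def deterministic_block():
    cfg = TaskConfig(TransitionSpec.deterministic(4), n_trials=100)
    recs = simulate_block(AgentParams(0.7, 0.1, 0.6), cfg, seed=8)
    return records_to_frame(recs, 0, 0, cfg)


def naive_block_nll(params, block, spec, variant="td1_hybrid"):
    """Literal trial-loop likelihood, written directly from the update rules.

    Deliberately independent of twostage.fitting: plain-python state, explicit
    history classification, explicit logistic probabilities.
    """
    v = [50.0, 50.0]
    q = [50.0, 50.0]
    choices = list(block["choice"])
    states = list(block["state"])
    rewards = list(block["reward"])
    prev_choice = None
    nll = 0.0
    for t in range(len(choices)):
        # model-based values
        if spec.condition == "stochastic":
            qmb = []
            for o in (0, 1):
                c = spec.common_map[o]
                qmb.append(spec.p_common * v[c] + (1 - spec.p_common) * v[1 - c])
        else:
            qmb = []
            for o in (0, 1):
                if t < 2:
                    qmb.append((v[0] + v[1]) / 2.0)
                    continue
                a1, a2 = choices[t - 1], choices[t - 2]
                if o == a1 == a2:
                    h = "SSS"
                elif o == a2 and o != a1:
                    h = "ALT"
                elif o == a1 and o != a2:
                    h = "S1"
                else:
                    h = "D12"
                out = spec.pattern.outcome[h]
                if spec.pattern.dialect == "absolute_state":
                    s_pred = int(out)
                else:
                    s_pred = states[t - 1] if out == "stay" else 1 - states[t - 1]
                qmb.append(v[s_pred])
        qh = [params.w * qmb[o] + (1 - params.w) * q[o] for o in (0, 1)]
        z = params.beta * (qh[1] - qh[0])
        if prev_choice is not None:
            z += params.rho * (1.0 if prev_choice == 1 else -1.0)
        zz = z if choices[t] == 1 else -z
        # -log P(choice) = -log sigmoid(zz), in the numerically exact form
        nll += math.log1p(math.exp(-zz)) if zz > -35 else -zz
        # updates: v of reached state, q_mf of chosen option
        r, s, c = rewards[t], states[t], choices[t]
        if variant.startswith("td1"):
            target = r
        elif variant.startswith("td0"):
            target = v[s]
        else:
            target = params.lam * r + (1 - params.lam) * v[s]
        v[s] = v[s] + params.alpha * (r - v[s])
        q[c] = q[c] + params.alpha * (target - q[c])
        prev_choice = c
    return nll
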