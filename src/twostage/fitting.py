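"""Block-wise maximum-likelihood estimation of the hybrid RL model.

The likelihood kernel (:func:`block_nll`) runs the agent's value updates
forward through an observed block and accumulates the negative log
probability of each first-stage choice under the logistic rule. Per-block
fits use bounded multi-start L-BFGS-B (Latin-hypercube starts), with a
profile-likelihood identifiability screen on the model-based weight ``w``
and BIC-based model comparison across TD variants.

The per-trial update order is: form q^MB and q^HYB from the previous trial's
cached values -> score the observed choice -> observe the reward -> update
the reached state's v and the chosen option's q^MF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .agents import VARIANTS, AgentParams
from .task import (
    BUILTIN_PATTERNS,
    TransitionSpec,
    classify_history,
    pattern_next_state,
)

__all__ = [
    "BlockData",
    "FitResult",
    "prepare_block",
    "infer_spec",
    "block_nll",
    "fit_block",
    "identifiability_check",
    "profile_w",
    "compare_models",
    "q_value_series",
    "PARAM_BOUNDS",
]

#: Optimizer box constraints per parameter.
PARAM_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 10.0),
    "w": (0.0, 1.0),
    "lam": (0.0, 1.0),
    "rho": (-5.0, 5.0),
}

_INIT_VALUE = 50.0  # reward-range midpoint


class SchemaError(ValueError):
    """A trial table misses required columns or holds malformed values."""


@dataclass
class BlockData:
    """Precomputed parameter-independent arrays for one block's likelihood."""

    choices: np.ndarray
    states: np.ndarray
    rewards: np.ndarray
    condition: str
    p_state_right: Optional[np.ndarray] = None  # P(state=1 | option), stochastic
    pred: Optional[np.ndarray] = None  # (n, 2) predicted state per option, -1 = undefined

    @property
    def n_trials(self) -> int:
        return len(self.choices)


def infer_spec(block: pd.DataFrame) -> TransitionSpec:
    """Reconstruct the block's TransitionSpec from its trial rows.

    Stochastic blocks: ``param`` is p_common and the common mapping is read
    off any trial's (choice, state, is_common) triple. Deterministic blocks:
    ``param`` indexes the built-in pattern.
    """
    condition = str(block["condition"].iloc[0])
    param = float(block["param"].iloc[0])
    if condition == "stochastic":
        ic = block["is_common"].astype("boolean")
        if ic.isna().all():
            raise SchemaError("stochastic block without is_common flags")
        i = int(ic.notna().to_numpy().argmax())
        choice = int(block["choice"].iloc[i])
        state = int(block["state"].iloc[i])
        common_state = state if bool(ic.iloc[i]) else 1 - state
        cm = [0, 0]
        cm[choice] = common_state
        cm[1 - choice] = 1 - common_state
        return TransitionSpec.stochastic(param, tuple(cm))
    if condition == "deterministic":
        return TransitionSpec.deterministic(BUILTIN_PATTERNS[int(param)])
    raise SchemaError(f"unknown condition {condition!r}")


def prepare_block(block: pd.DataFrame, spec: Optional[TransitionSpec] = None) -> BlockData:
    """Extract and precompute everything the likelihood needs from a block."""
    required = {"choice", "state", "reward"}
    missing = required - set(block.columns)
    if missing:
        raise SchemaError(f"block misses columns: {sorted(missing)}")
    if spec is None:
        spec = infer_spec(block)
    choices = block["choice"].to_numpy(dtype=np.int64)
    states = block["state"].to_numpy(dtype=np.int64)
    rewards = block["reward"].to_numpy(dtype=float)
    if not (np.isfinite(rewards).all() and np.isin(choices, (0, 1)).all()
            and np.isin(states, (0, 1)).all()):
        raise SchemaError("block holds non-finite rewards or non-binary codes")
    n = len(choices)
    if spec.condition == "stochastic":
        p = spec.p_common
        p_right = np.array(
            [p if spec.common_map[o] == 1 else 1.0 - p for o in (0, 1)]
        )
        return BlockData(choices, states, rewards, "stochastic", p_state_right=p_right)
    pred = np.full((n, 2), -1, dtype=np.int64)
    for t in range(2, n):
        for o in (0, 1):
            h = classify_history(o, choices[t - 1], choices[t - 2])
            pred[t, o] = pattern_next_state(h, states[t - 1], spec.pattern)
    return BlockData(choices, states, rewards, "deterministic", pred=pred)


def _forward(
    bd: BlockData,
    alpha: float,
    beta: float,
    w: float,
    rho: float,
    lam: float,
    variant: str,
    collect: bool = False,
):
    """Shared forward pass: returns nll (and q-difference series if asked)."""
    choices, states, rewards = bd.choices, bd.states, bd.rewards
    n = bd.n_trials
    v0 = v1 = q0 = q1 = _INIT_VALUE
    stochastic = bd.condition == "stochastic"
    if stochastic:
        pr0, pr1 = bd.p_state_right
    else:
        pred = bd.pred
    td1 = variant.startswith("td1")
    td0 = variant.startswith("td0")
    prev = -1
    nll = 0.0
    mb_diff = np.empty(n) if collect else None
    mf_diff = np.empty(n) if collect else None
    for t in range(n):
        if stochastic:
            qmb0 = pr0 * v1 + (1.0 - pr0) * v0
            qmb1 = pr1 * v1 + (1.0 - pr1) * v0
        else:
            p0 = pred[t, 0]
            p1_ = pred[t, 1]
            m = 0.5 * (v0 + v1)
            qmb0 = m if p0 < 0 else (v1 if p0 == 1 else v0)
            qmb1 = m if p1_ < 0 else (v1 if p1_ == 1 else v0)
        d = w * (qmb1 - qmb0) + (1.0 - w) * (q1 - q0)
        z = beta * d
        if prev >= 0:
            z += rho if prev == 1 else -rho
        c = choices[t]
        zz = z if c == 1 else -z
        # -log sigmoid(zz), numerically stable
        if zz < -35.0:
            nll -= zz
        else:
            nll += math.log1p(math.exp(-zz))
        if collect:
            mb_diff[t] = qmb1 - qmb0
            mf_diff[t] = q1 - q0
        r = rewards[t]
        s = states[t]
        v_reached = v1 if s == 1 else v0
        if td1:
            target = r
        elif td0:
            target = v_reached
        else:
            target = lam * r + (1.0 - lam) * v_reached
        if s == 1:
            v1 += alpha * (r - v1)
        else:
            v0 += alpha * (r - v0)
        if c == 1:
            q1 += alpha * (target - q1)
        else:
            q0 += alpha * (target - q0)
        prev = c
    if collect:
        return nll, mb_diff, mf_diff
    return nll


def block_nll(
    params: AgentParams,
    block,
    spec: Optional[TransitionSpec] = None,
    variant: str = "td1_hybrid",
) -> float:
    """Negative log-likelihood (nats) of a block's first-stage choices.

    ``block`` may be a trial DataFrame or a precomputed :class:`BlockData`.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    bd = block if isinstance(block, BlockData) else prepare_block(block, spec)
    nll = _forward(bd, params.alpha, params.beta, params.w, params.rho, params.lam,
                   variant)
    if not math.isfinite(nll):
        raise FloatingPointError("non-finite likelihood")
    return nll


def q_value_series(
    params: AgentParams, block, spec: Optional[TransitionSpec] = None,
    variant: str = "td1_hybrid",
):
    """Per-trial (q^MB, q^MF) difference series (option 1 minus option 0)."""
    bd = block if isinstance(block, BlockData) else prepare_block(block, spec)
    _, mb, mf = _forward(bd, params.alpha, params.beta, params.w, params.rho,
                         params.lam, variant, collect=True)
    return mb, mf


@dataclass
class FitResult:
    """Outcome of one block-level MLE."""

    params: AgentParams
    nll: float
    n_trials: int
    bic: float
    converged: bool
    w_identified: bool
    n_starts: int
    variant: str = "td1_hybrid"
    block_id: object = None

    @property
    def k(self) -> int:
        return len(VARIANTS[self.variant])


def _vector_to_params(x: np.ndarray, names: Sequence[str]) -> AgentParams:
    kw = dict(zip(names, (float(v) for v in x)))
    return AgentParams(**kw)


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def fit_block(
    block,
    spec: Optional[TransitionSpec] = None,
    variant: str = "td1_hybrid",
    n_starts: int = 10,
    seed: int = 0,
    check_identifiability: bool = True,
    block_id=None,
) -> FitResult:
    """Best-of-``n_starts`` bounded MLE of the variant's free parameters.

    Starts are a seeded Latin hypercube over the parameter box plus one
    center start; the fit is deterministic given ``seed``. ``w_identified``
    applies the profile-likelihood screen (see
    :func:`identifiability_check`) when the variant frees ``w``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    bd = block if isinstance(block, BlockData) else prepare_block(block, spec)
    if bd.n_trials < 20:
        raise ValueError(f"need >= 20 trials to fit, got {bd.n_trials}")
    names = VARIANTS[variant]
    bounds = [PARAM_BOUNDS[p] for p in names]

    def objective(x: np.ndarray) -> float:
        p = _vector_to_params(_clip_to_bounds(x, bounds), names)
        return _forward(bd, p.alpha, p.beta, p.w, p.rho, p.lam, variant)

    starts = _lhs_starts(bounds, n_starts, seed)
    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    params = _vector_to_params(best.x, names)
    n = bd.n_trials
    bic = 2.0 * best.fun + len(names) * math.log(n)
    result = FitResult(
        params=params,
        nll=float(best.fun),
        n_trials=n,
        bic=bic,
        converged=any_converged,
        w_identified=True,
        n_starts=len(starts),
        variant=variant,
        block_id=block_id,
    )
    if check_identifiability and "w" in names:
        result.w_identified = identifiability_check(bd, None, result)
    return result


def _lhs_starts(bounds, n_starts: int, seed: int) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    center = (lo + hi) / 2.0
    if n_starts <= 1:
        return center[None, :]
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    u = sampler.random(n_starts - 1)
    # beta explores the low end where fitted values live (0-100 point scale)
    pts = lo + u * (hi - lo)
    bidx = [i for i, b in enumerate(bounds) if b == PARAM_BOUNDS["beta"]]
    for i in bidx:
        pts[:, i] = PARAM_BOUNDS["beta"][1] * u[:, i] ** 2
    return np.vstack([center[None, :], pts])


def profile_w(
    block,
    spec: Optional[TransitionSpec] = None,
    best: Optional[FitResult] = None,
    variant: str = "td1_hybrid",
    grid_size: int = 21,
) -> np.ndarray:
    """Profile negative log-likelihood over a w grid.

    At each grid value of ``w`` the remaining parameters are re-optimized,
    warm-started from the neighbouring grid point (continuation), seeded from
    the best fit when available.
    """
    bd = block if isinstance(block, BlockData) else prepare_block(block, spec)
    names = VARIANTS[variant]
    if "w" not in names:
        raise ValueError(f"variant {variant!r} does not free w")
    free = [p for p in names if p != "w"]
    bounds = [PARAM_BOUNDS[p] for p in free]
    grid = np.linspace(0.0, 1.0, grid_size)
    if best is not None:
        x_best = np.array([getattr(best.params, p) for p in free])
    else:
        x_best = np.array([(b[0] + b[1]) / 2.0 for b in bounds])

    def objective(xf, w):
        kw = dict(zip(free, _clip_to_bounds(np.asarray(xf), bounds)))
        kw["w"] = w
        p = AgentParams(**{k: float(v) for k, v in kw.items()})
        return _forward(bd, p.alpha, p.beta, p.w, p.rho, p.lam, variant)

    # warm-start continuation from the neighbouring grid point, but always
    # also try the best fit's nuisance parameters: the continuation path can
    # get trapped on the flat beta = 0 plateau
    prof = np.empty(grid_size)
    x_prev = x_best
    for i, w in enumerate(grid):
        results = []
        for x0 in (x_prev, x_best):
            results.append(optimize.minimize(objective, x0, args=(w,),
                                             method="L-BFGS-B", bounds=bounds))
        res = min(results, key=lambda r: r.fun)
        prof[i] = res.fun
        x_prev = res.x
    return prof


def identifiability_check(
    block,
    spec: Optional[TransitionSpec],
    best: FitResult,
    tol: float = 0.01,
    qcorr_tol: float = 0.999,
    grid_size: int = 21,
) -> bool:
    """Is the model-based weight ``w`` constrained by this block's data?

    Not identified when the model-based and model-free Q-difference series
    are (nearly) collinear or the model-based series is constant — ``w`` is
    then inert — or when the profile likelihood over ``w`` is flat (range
    below ``tol`` nats).
    """
    bd = block if isinstance(block, BlockData) else prepare_block(block, spec)
    mb, mf = q_value_series(best.params, bd, variant=best.variant)
    sd_mb, sd_mf = mb.std(), mf.std()
    if sd_mb < 1e-9:
        return False
    if sd_mf > 1e-9:
        corr = float(np.corrcoef(mb, mf)[0, 1])
        if abs(corr) > qcorr_tol:
            return False
    prof = profile_w(bd, best=best, variant=best.variant, grid_size=grid_size)
    return bool(prof.max() - prof.min() > tol)


def compare_models(
    blocks,
    variants: Sequence[str] = ("td1_hybrid", "td0_hybrid", "tdlam_hybrid",
                               "td1_persev", "tdlam_persev"),
    specs=None,
    n_starts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean BIC per model variant over a list of blocks.

    ``blocks`` is a sequence of trial DataFrames (or BlockData with
    ``specs`` resolved beforehand). Returns one row per variant with mean
    BIC and mean nll, sorted best first.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one block")
    if specs is None:
        specs = [None] * len(blocks)
    rows = []
    for variant in variants:
        bics, nlls = [], []
        for i, (blk, sp) in enumerate(zip(blocks, specs)):
            fit = fit_block(blk, sp, variant=variant, n_starts=n_starts,
                            seed=seed + i, check_identifiability=False)
            bics.append(fit.bic)
            nlls.append(fit.nll)
        rows.append({"variant": variant, "k": len(VARIANTS[variant]),
                     "mean_bic": float(np.mean(bics)),
                     "mean_nll": float(np.mean(nlls))})
    return (pd.DataFrame(rows)
            .sort_values("mean_bic")
            .reset_index(drop=True))
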