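"""Synthetic cohorts: full experiments with known ground truth.

A cohort is ``n_subjects`` hybrid agents, each completing (by default) the
eight-block design — four stochastic blocks with common-transition
probability 0.6/0.7/0.8/0.9 and four deterministic pattern blocks — of 100
trials each, in randomized order with counterbalanced common mappings.
Agent parameters are drawn per subject from configurable distributions, and
cursor crossings are generated from the Bayesian ideal observer's beliefs
(independently of the agent's model-based weight ``w``, so structure
knowledge and model-based choice can dissociate in the synthetic data; set
``design.cursor_mode`` to change this). Everything derives deterministically
from ``master_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

from .agents import AgentParams, simulate_block
from .beliefs import MouseParams
from .fitting import fit_block, prepare_block
from .task import TaskConfig, TransitionSpec

__all__ = [
    "CohortDesign",
    "Cohort",
    "default_blocks",
    "default_param_dists",
    "point_mass_dists",
    "records_to_frame",
    "sample_cohort",
    "fit_cohort",
    "recovery_experiment",
]

STOCHASTIC_PS = (0.6, 0.7, 0.8, 0.9)
PATTERN_IDS = (1, 2, 3, 4)


def default_blocks(n_trials: int = 100,
                   stochastic_ps=STOCHASTIC_PS,
                   pattern_ids=PATTERN_IDS) -> List[TaskConfig]:
    """The eight-block design: stochastic p grid plus the pattern blocks."""
    blocks = [
        TaskConfig(TransitionSpec.stochastic(p), n_trials=n_trials)
        for p in stochastic_ps
    ]
    blocks += [
        TaskConfig(TransitionSpec.deterministic(pid), n_trials=n_trials)
        for pid in pattern_ids
    ]
    return blocks


def default_param_dists() -> Dict[str, Callable]:
    """Per-subject parameter samplers mirroring the fitted medians.

    alpha ~ Beta(3.5, 1.5) (median ~0.72), beta ~ LogNormal(ln 0.1, 0.5)
    (median 0.1 on the 0-100 point scale), w ~ Uniform(0, 1); cursor gain
    and noise are point masses at the generative defaults.
    """
    return {
        "alpha": lambda rng: float(rng.beta(3.5, 1.5)),
        "beta": lambda rng: float(rng.lognormal(np.log(0.1), 0.5)),
        "w": lambda rng: float(rng.uniform(0.0, 1.0)),
        "gain": lambda rng: 500.0,
        "noise_sd": lambda rng: 50.0,
    }


def point_mass_dists(**values) -> Dict[str, Callable]:
    """Degenerate samplers: every subject shares the given parameter values."""
    dists = default_param_dists()
    for k, v in values.items():
        if k not in dists:
            raise ValueError(f"unknown parameter {k!r}")
        dists[k] = (lambda val: (lambda rng: float(val)))(v)
    return dists


@dataclass
class CohortDesign:
    """Design of a synthetic experiment."""

    n_subjects: int = 57
    blocks: List[TaskConfig] = field(default_factory=default_blocks)
    param_dists: Dict[str, Callable] = field(default_factory=default_param_dists)
    master_seed: int = 0
    randomize_block_order: bool = True
    counterbalance_mapping: bool = True
    cursor_mode: str = "bayesian"  # or "none"
    variant: str = "td1_hybrid"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.blocks:
            raise ValueError("block list must be non-empty")
        if self.cursor_mode not in ("bayesian", "none"):
            raise ValueError(f"unknown cursor_mode {self.cursor_mode!r}")


@dataclass
class Cohort:
    """A sampled cohort: trial table, ground-truth parameters, design."""

    trials: pd.DataFrame
    truth: pd.DataFrame
    design: CohortDesign


def records_to_frame(records, subject_id, block_id, config: TaskConfig) -> pd.DataFrame:
    spec = config.spec
    return pd.DataFrame({
        "subject_id": subject_id,
        "block_id": block_id,
        "condition": spec.condition,
        "param": spec.param,
        "trial": [r.trial for r in records],
        "choice": [r.choice for r in records],
        "state": [r.state for r in records],
        "is_common": pd.array([r.is_common for r in records], dtype="boolean"),
        "reward": [r.reward for r in records],
        "crossing_x": np.array(
            [np.nan if r.crossing_x is None else r.crossing_x for r in records]
        ),
        "stay": pd.array([r.stay for r in records], dtype="boolean"),
        "reward_left": [r.reward_left for r in records],
        "reward_right": [r.reward_right for r in records],
    })


def sample_cohort(design: CohortDesign) -> Cohort:
    """Simulate the full cohort; reproducible from ``design.master_seed``."""
    root = np.random.SeedSequence(design.master_seed)
    subject_seeds = root.spawn(design.n_subjects)
    frames, truth_rows = [], []
    for s, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        params = AgentParams(
            alpha=design.param_dists["alpha"](rng),
            beta=design.param_dists["beta"](rng),
            w=design.param_dists["w"](rng),
        )
        mouse = None
        gain = design.param_dists["gain"](rng)
        noise = design.param_dists["noise_sd"](rng)
        if design.cursor_mode == "bayesian":
            mouse = MouseParams(gain=gain, noise_sd=noise)
        order = (rng.permutation(len(design.blocks))
                 if design.randomize_block_order
                 else np.arange(len(design.blocks)))
        truth_rows.append({
            "subject_id": s, "alpha": params.alpha, "beta": params.beta,
            "w": params.w, "gain": gain, "noise_sd": noise,
        })
        for b, bi in enumerate(order):
            config = design.blocks[bi]
            spec = config.spec
            if (design.counterbalance_mapping and spec.condition == "stochastic"
                    and rng.random() < 0.5):
                spec = TransitionSpec.stochastic(
                    spec.p_common, (1 - spec.common_map[0], 1 - spec.common_map[1])
                )
                config = TaskConfig(spec, config.n_trials, config.walk,
                                    config.screen_width_px, config.line_frac)
            records = simulate_block(
                params, config, variant=design.variant, mouse=mouse, rng=rng
            )
            frames.append(records_to_frame(records, s, b, config))
    trials = pd.concat(frames, ignore_index=True)
    return Cohort(trials=trials, truth=pd.DataFrame(truth_rows), design=design)


def fit_cohort(
    cohort: Cohort,
    variant: str = "td1_hybrid",
    n_starts: int = 10,
    seed: int = 0,
    check_identifiability: bool = True,
    conditions=("stochastic", "deterministic"),
) -> pd.DataFrame:
    """Fit every block of every subject; one row per block."""
    rows = []
    for (sid, bid), blk in cohort.trials.groupby(["subject_id", "block_id"],
                                                 sort=True):
        cond = blk["condition"].iloc[0]
        if cond not in conditions:
            continue
        bd = prepare_block(blk)
        fit = fit_block(
            bd, variant=variant, n_starts=n_starts,
            seed=int(seed + 7919 * sid + bid),
            check_identifiability=check_identifiability, block_id=(sid, bid),
        )
        rows.append({
            "subject_id": sid, "block_id": bid, "condition": cond,
            "param": blk["param"].iloc[0],
            "alpha": fit.params.alpha, "beta": fit.params.beta, "w": fit.params.w,
            "rho": fit.params.rho, "lam": fit.params.lam,
            "nll": fit.nll, "bic": fit.bic, "n_trials": fit.n_trials,
            "converged": fit.converged, "w_identified": fit.w_identified,
            "n_starts": fit.n_starts, "variant": variant,
        })
    return pd.DataFrame(rows)


def recovery_experiment(
    design: CohortDesign,
    variant: str = "td1_hybrid",
    n_starts: int = 10,
    check_identifiability: bool = True,
    conditions=("stochastic",),
) -> dict:
    """Simulate a cohort, refit every block, and score parameter recovery.

    Subject-level recovered values average the block-wise estimates over
    identified blocks (``w``) or all blocks (``alpha``, ``beta``). Returns
    the cohort, the block-level fit table, a subject-level true-vs-recovered
    table, and per-parameter Pearson r, bias, and RMSE, plus the fraction of
    blocks flagged non-identified.
    """
    cohort = sample_cohort(design)
    fits = fit_cohort(
        cohort, variant=variant, n_starts=n_starts,
        seed=design.master_seed + 1, check_identifiability=check_identifiability,
        conditions=conditions,
    )
    w_sub = (fits[fits["w_identified"]].groupby("subject_id")["w"].mean()
             if check_identifiability else fits.groupby("subject_id")["w"].mean())
    ab_sub = fits.groupby("subject_id")[["alpha", "beta"]].mean()
    recovered = ab_sub.join(w_sub.rename("w"), how="left").reset_index()
    table = cohort.truth.merge(
        recovered, on="subject_id", suffixes=("_true", "_hat")
    )
    metrics = {}
    for p in ("alpha", "beta", "w"):
        t = table[f"{p}_true"].to_numpy(float)
        h = table[f"{p}_hat"].to_numpy(float)
        ok = np.isfinite(t) & np.isfinite(h)
        t, h = t[ok], h[ok]
        r = float(np.corrcoef(t, h)[0, 1]) if len(t) > 2 else float("nan")
        metrics[p] = {
            "pearson_r": r,
            "bias": float(np.mean(h - t)),
            "rmse": float(np.sqrt(np.mean((h - t) ** 2))),
            "n_subjects": int(len(t)),
        }
    return {
        "cohort": cohort,
        "fits": fits,
        "table": table,
        "metrics": metrics,
        "frac_non_identified": float(1.0 - fits["w_identified"].mean()),
    }
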