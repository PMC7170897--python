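"""Behavioral and mouse-tracking measures at the block, subject, and cohort level.

Three individual-level quantities anchor the analyses:

* **normalized reward rate** — points earned minus the within-block average
  of the two states' realized reward schedules (removing schedule luck);
* **stay regressions** — per-subject logistic regressions of the decision to
  repeat the previous first-stage choice on the previous trial's reward
  (restricted to rare transitions, or with a reward x transition-type
  interaction); a negative rare-trial slope is the model-based signature;
* **cursor structure measure** — the signed pixel distance of the cursor's
  line crossing from the midline, positive toward the side where the
  correct (common or pattern-predicted) state appears.

Logistic fits use a weak L2 penalty (strength 1e-4) as a guard against
complete separation in small rare-trial samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .fitting import SchemaError, infer_spec
from .task import TransitionSpec, classify_history, pattern_next_state

__all__ = [
    "normalized_reward_rate",
    "stay_regression_rare",
    "stay_regression_interaction",
    "correct_side",
    "cursor_structure_measure",
    "binned_curves",
    "belief_distance_curve",
    "cohort_statistics",
    "subject_measures",
    "rare_slope_by_w",
    "interpolate_sign_change",
]

_L2_STRENGTH = 1e-4  # separation guard; C = 1/strength in sklearn terms


def normalized_reward_rate(block: pd.DataFrame, per_trial: bool = False) -> float:
    """Points earned above the block's schedule baseline.

    Subtracts ``n_trials`` times the mean over trials of the two states'
    average realized reward from the total reward received; ``per_trial``
    divides by the trial count. Zero is the expected value of a chooser that
    tracks the schedule average (e.g. a uniform random chooser under
    symmetric transitions).
    """
    for col in ("reward", "reward_left", "reward_right"):
        if col not in block.columns or block[col].isna().any():
            raise SchemaError(f"normalized reward rate needs complete {col!r}")
    total = float(block["reward"].sum())
    baseline = float(
        ((block["reward_left"] + block["reward_right"]) / 2.0).sum()
    )
    out = total - baseline
    return out / len(block) if per_trial else out


def _penalized_logit_slopes(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Slopes of a weakly L2-penalized logistic regression (with intercept)."""
    model = LogisticRegression(C=1.0 / _L2_STRENGTH, solver="lbfgs", max_iter=1000)
    model.fit(X, y)
    return model.coef_[0]


def _stay_design(blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-trial rows (from trial 2 on, within block) with lagged predictors."""
    need = {"choice", "reward", "is_common"}
    if not need <= set(blocks.columns):
        raise SchemaError(f"stay regression needs columns {sorted(need)}")
    group_cols = [c for c in ("subject_id", "block_id") if c in blocks.columns]
    parts = []
    grouped = blocks.groupby(group_cols, sort=False) if group_cols else [(None, blocks)]
    for _, g in grouped:
        g = g.reset_index(drop=True)
        if len(g) < 2:
            continue
        parts.append(pd.DataFrame({
            "stay": (g["choice"].to_numpy()[1:] == g["choice"].to_numpy()[:-1])
            .astype(int),
            "prev_reward": g["reward"].to_numpy(float)[:-1],
            "prev_common": g["is_common"].astype("boolean").to_numpy()[:-1],
        }))
    if not parts:
        raise SchemaError("no usable trials (blocks shorter than 2)")
    return pd.concat(parts, ignore_index=True)


def stay_regression_rare(blocks: pd.DataFrame, min_trials: int = 10) -> float:
    """Logistic slope of stay on the previous reward, rare-transition trials only.

    Pools one subject's stochastic trials (from trial 2 on, per block) whose
    *previous* transition was rare. Negative slopes mark model-based choice.
    """
    d = _stay_design(blocks)
    d = d[d["prev_common"] == False]  # noqa: E712 (nullable boolean)
    if len(d) < min_trials:
        raise ValueError(
            f"need >= {min_trials} usable rare-transition trials, got {len(d)}"
        )
    if d["stay"].nunique() < 2:
        # all stays (or all switches): slope undefined; report 0 with the guard
        return 0.0
    X = d[["prev_reward"]].to_numpy(float)
    return float(_penalized_logit_slopes(X, d["stay"].to_numpy())[0])


def stay_regression_interaction(blocks: pd.DataFrame, min_trials: int = 10) -> float:
    """Interaction slope of stay ~ prev_reward * prev_transition_type.

    The transition indicator is +/-0.5 (common/rare), so the interaction is
    the difference between the common- and rare-trial reward slopes; ~0 for
    purely model-free agents.
    """
    d = _stay_design(blocks)
    d = d[d["prev_common"].notna()]
    if len(d) < min_trials:
        raise ValueError(f"need >= {min_trials} usable trials, got {len(d)}")
    if d["stay"].nunique() < 2:
        return 0.0
    common = d["prev_common"].astype(bool).to_numpy().astype(float) - 0.5
    r = d["prev_reward"].to_numpy(float)
    X = np.column_stack([r, common, r * common])
    return float(_penalized_logit_slopes(X, d["stay"].to_numpy())[2])


def correct_side(block: pd.DataFrame, spec: Optional[TransitionSpec] = None) -> np.ndarray:
    """Per-trial correct state side (0 = left, 1 = right), -1 where undefined.

    Stochastic: the chosen option's common-transition state. Deterministic:
    the pattern-predicted state (undefined during the two warm-up trials).
    """
    if spec is None:
        spec = infer_spec(block)
    choices = block["choice"].to_numpy(int)
    n = len(choices)
    if spec.condition == "stochastic":
        return np.array([spec.common_map[c] for c in choices])
    states = block["state"].to_numpy(int)
    out = np.full(n, -1)
    for t in range(2, n):
        h = classify_history(choices[t], choices[t - 1], choices[t - 2])
        out[t] = pattern_next_state(h, states[t - 1], spec.pattern)
    return out


def cursor_structure_measure(
    block: pd.DataFrame,
    spec: Optional[TransitionSpec] = None,
    binary: bool = False,
    per_trial: bool = False,
):
    """Mean signed pixel distance of the line crossing toward the correct side.

    Positive when the cursor crossed on the side where the correct state was
    to appear, negative otherwise. Trials with a missing crossing or an
    undefined correct side (deterministic warm-up) are excluded. With
    ``binary=True`` returns the fraction of crossings on the correct side
    instead (exact midline crossings count half).
    """
    if "crossing_x" not in block.columns:
        raise SchemaError("cursor measure needs a crossing_x column")
    side = correct_side(block, spec)
    x = block["crossing_x"].to_numpy(float)
    usable = (side >= 0) & np.isfinite(x)
    if not usable.any():
        raise ValueError("no usable trials with crossings and a defined correct side")
    signed = np.where(side[usable] == 1, x[usable], -x[usable])
    if binary:
        vals = (signed > 0).astype(float)
        vals[signed == 0] = 0.5
        return vals if per_trial else float(vals.mean())
    return signed if per_trial else float(signed.mean())


def binned_curves(
    blocks: pd.DataFrame,
    trial_bin: int = 5,
    first_n: int = 40,
    value_cols: Sequence[str] = ("belief_right", "crossing_x"),
) -> pd.DataFrame:
    """Early-learning curves: mean belief and cursor position per trial bin.

    Restricts to the first ``first_n`` trials of each block, bins trials in
    groups of ``trial_bin`` (trials 1-5, 6-10, ...), and averages the value
    columns per (condition, param, bin). Empty bins are absent, not
    interpolated.
    """
    cols = [c for c in value_cols if c in blocks.columns]
    if not cols:
        raise SchemaError(f"none of {list(value_cols)} present")
    d = blocks[blocks["trial"] < first_n].copy()
    d["trial_bin"] = d["trial"] // trial_bin
    out = (
        d.groupby(["condition", "param", "trial_bin"], sort=True)[cols]
        .mean()
        .reset_index()
    )
    out["trial_lo"] = out["trial_bin"] * trial_bin + 1
    out["trial_hi"] = (out["trial_bin"] + 1) * trial_bin
    return out


def belief_distance_curve(
    blocks: pd.DataFrame, belief_bin: float = 0.1
) -> pd.DataFrame:
    """Mean rightward cursor displacement per belief bin (width ``belief_bin``).

    Bins the posterior belief that the right-hand state is coming and
    averages the crossing x within each (condition, param, bin); the map is
    approximately linear under the generative cursor model.
    """
    need = {"belief_right", "crossing_x"}
    if not need <= set(blocks.columns):
        raise SchemaError(f"needs columns {sorted(need)}")
    d = blocks.dropna(subset=["belief_right", "crossing_x"]).copy()
    nbins = int(round(1.0 / belief_bin))
    idx = np.minimum((d["belief_right"] / belief_bin).astype(int), nbins - 1)
    d["belief_bin"] = idx
    out = (
        d.groupby(["condition", "param", "belief_bin"], sort=True)
        .agg(belief_mid=("belief_right", "mean"),
             crossing_x=("crossing_x", "mean"),
             n=("crossing_x", "size"))
        .reset_index()
    )
    return out


def cohort_statistics(measures: pd.DataFrame, columns: Optional[Sequence[str]] = None):
    """Pairwise Pearson correlations and one-sample t-tests across subjects.

    Returns ``(correlations, tests)``: correlations holds r, t(df), and p for
    each pair of measure columns; tests holds the one-sample t-test of each
    column against zero. Zero-variance columns are flagged (r = NaN).
    """
    if columns is None:
        columns = [c for c in measures.columns
                   if measures[c].dtype.kind in "fi" and c != "subject_id"]
    n = len(measures)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    corr_rows = []
    for i, a in enumerate(columns):
        for b in columns[i:]:
            x = measures[a].to_numpy(float)
            y = measures[b].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            m = len(x)
            if m < 3 or x.std() == 0 or y.std() == 0:
                r, t, p = math.nan, math.nan, math.nan
            elif a == b:
                r, t, p = 1.0, math.inf, 0.0
            else:
                r, p = stats.pearsonr(x, y)
                t = r * math.sqrt((m - 2) / max(1.0 - r * r, 1e-300))
            corr_rows.append({"x": a, "y": b, "r": r, "t": t, "df": m - 2, "p": p})
    test_rows = []
    for a in columns:
        x = measures[a].to_numpy(float)
        x = x[np.isfinite(x)]
        res = stats.ttest_1samp(x, 0.0)
        test_rows.append({"measure": a, "mean": float(x.mean()),
                          "sem": float(stats.sem(x)) if len(x) > 1 else math.nan,
                          "t": float(res.statistic), "df": len(x) - 1,
                          "p": float(res.pvalue)})
    return pd.DataFrame(corr_rows), pd.DataFrame(test_rows)


def rare_slope_by_w(
    w_grid: Sequence[float],
    n_agents: int = 200,
    alpha: float = 0.7,
    beta: float = 0.1,
    p_common: float = 0.7,
    n_blocks: int = 4,
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean rare-transition stay slope of simulated hybrid agents per ``w``.

    For each ``w`` on the grid, simulates ``n_agents`` agents (``n_blocks``
    stochastic blocks of ``n_trials`` each) and fits the per-agent logistic
    regression of stay on the previous trial's reward, restricted to trials
    following rare transitions. The sign change of the mean slope across the
    grid locates the boundary between model-free-looking and
    model-based-looking choice.
    """
    from .agents import AgentParams, simulate_block
    from .cohort import records_to_frame
    from .task import TaskConfig, TransitionSpec

    root = np.random.SeedSequence(seed)
    rows = []
    for w in w_grid:
        params = AgentParams(alpha=alpha, beta=beta, w=float(w))
        slopes = []
        for sseq in root.spawn(n_agents):
            rng = np.random.default_rng(sseq)
            frames = []
            for b in range(n_blocks):
                cfg = TaskConfig(TransitionSpec.stochastic(p_common),
                                 n_trials=n_trials)
                recs = simulate_block(params, cfg, rng=rng)
                frames.append(records_to_frame(recs, 0, b, cfg))
            slopes.append(stay_regression_rare(pd.concat(frames,
                                                         ignore_index=True)))
        slopes = np.asarray(slopes)
        rows.append({"w": float(w), "mean_slope": slopes.mean(),
                     "se": slopes.std(ddof=1) / math.sqrt(len(slopes)),
                     "n_agents": len(slopes)})
    return pd.DataFrame(rows)


def interpolate_sign_change(ws, means) -> float:
    """Linearly interpolated zero crossing of a mean-slope curve over w."""
    ws = np.asarray(ws, dtype=float)
    means = np.asarray(means, dtype=float)
    signs = np.sign(means)
    idx = np.where(np.diff(signs) != 0)[0]
    if len(idx) == 0:
        raise ValueError("mean slope does not change sign on the grid")
    i = int(idx[0])
    return float(ws[i] - means[i] * (ws[i + 1] - ws[i]) / (means[i + 1] - means[i]))


def subject_measures(
    trials: pd.DataFrame,
    fits: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Subject-level summary table of the core measures.

    Per subject: mean normalized reward rate and mean cursor measure per
    condition, the rare-transition stay slope and the reward x transition
    interaction (stochastic trials), and — when a block-level fit table is
    supplied — the mean fitted ``w`` over identified blocks per condition.
    """
    rows = []
    for sid, g in trials.groupby("subject_id", sort=True):
        row = {"subject_id": sid}
        for cond, gc in g.groupby("condition"):
            vals_r, vals_c = [], []
            for _, blk in gc.groupby("block_id"):
                vals_r.append(normalized_reward_rate(blk, per_trial=True))
                try:
                    vals_c.append(cursor_structure_measure(blk))
                except (ValueError, SchemaError):
                    pass
            row[f"reward_rate_{cond}"] = float(np.mean(vals_r))
            if vals_c:
                row[f"cursor_{cond}"] = float(np.mean(vals_c))
        stoch = g[g["condition"] == "stochastic"]
        if len(stoch):
            try:
                row["stay_slope_rare"] = stay_regression_rare(stoch)
                row["interaction_coef"] = stay_regression_interaction(stoch)
            except ValueError:
                pass
        rows.append(row)
    out = pd.DataFrame(rows)
    if fits is not None:
        wmeans = (
            fits[fits["w_identified"]]
            .groupby(["subject_id", "condition"])["w"]
            .mean()
            .unstack()
            .rename(columns=lambda c: f"w_{c}")
            .reset_index()
        )
        out = out.merge(wmeans, on="subject_id", how="left")
    return out
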