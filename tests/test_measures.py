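"""Behavioral and mouse-tracking measures."""

import numpy as np
import pandas as pd
import pytest

from twostage import AgentParams, TaskConfig, TransitionSpec
from twostage.beliefs import MouseParams, append_beliefs
from twostage.fitting import SchemaError
from twostage.measures import (
    belief_distance_curve,
    binned_curves,
    cohort_statistics,
    correct_side,
    cursor_structure_measure,
    normalized_reward_rate,
    stay_regression_interaction,
    stay_regression_rare,
    subject_measures,
)

from conftest import make_subject_frame


def _stochastic_frame(crossings, common_map=(0, 1), choices=None):
    """Small hand-built stochastic block with known correct sides."""
    n = len(crossings)
    choices = [0] * n if choices is None else choices
    # every trial a common transition: state = common_map[choice]
    states = [common_map[c] for c in choices]
    return pd.DataFrame({
        "subject_id": 0, "block_id": 0, "condition": "stochastic",
        "param": 0.8, "trial": range(n), "choice": choices, "state": states,
        "is_common": pd.array([True] * n, dtype="boolean"),
        "reward": 50.0, "crossing_x": crossings,
        "stay": pd.array([None] + [True] * (n - 1), dtype="boolean"),
        "reward_left": 50.0, "reward_right": 50.0,
    })


class TestNormalizedRewardRate:
    def test_average_earner_scores_zero(self, rng):
        n = 40
        left = rng.uniform(0, 100, n)
        right = rng.uniform(0, 100, n)
        df = pd.DataFrame({
            "reward": (left + right) / 2.0,
            "reward_left": left, "reward_right": right,
        })
        assert normalized_reward_rate(df) == pytest.approx(0.0, abs=1e-9)

    def test_best_state_chooser_is_positive(self, rng):
        n = 40
        left = rng.uniform(0, 100, n)
        right = rng.uniform(0, 100, n)
        df = pd.DataFrame({
            "reward": np.maximum(left, right),
            "reward_left": left, "reward_right": right,
        })
        assert normalized_reward_rate(df) > 0

    def test_uniform_random_chooser_near_zero(self):
        """A chooser ignoring values earns the schedule average on average."""
        vals = []
        for seed in range(40):
            cfg = TaskConfig(TransitionSpec.stochastic(0.8), n_trials=100)
            df = make_subject_frame(AgentParams(0.7, 0.0, 0.5), [cfg],
                                    seed=9000 + seed)
            vals.append(normalized_reward_rate(df, per_trial=True))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.05

    def test_missing_schedule_columns_raise(self):
        with pytest.raises(SchemaError):
            normalized_reward_rate(pd.DataFrame({"reward": [1.0]}))


class TestStayRegressions:
    @pytest.mark.parametrize("w, expect_sign", [(0.0, 1), (1.0, -1)])
    def test_rare_slope_sign_tracks_w(self, w, expect_sign):
        slopes = []
        for a in range(25):
            cfgs = [TaskConfig(TransitionSpec.stochastic(p), n_trials=100)
                    for p in (0.6, 0.7, 0.8, 0.9)]
            df = make_subject_frame(AgentParams(0.7, 0.1, w), cfgs,
                                    seed=17000 + 31 * a)
            slopes.append(stay_regression_rare(df))
        mean = np.mean(slopes)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert np.sign(mean) == expect_sign and abs(mean) > 2 * se

    def test_model_based_interaction_nonzero(self):
        coefs = []
        for a in range(25):
            cfgs = [TaskConfig(TransitionSpec.stochastic(0.7), n_trials=100)
                    for _ in range(4)]
            df = make_subject_frame(AgentParams(0.7, 0.1, 1.0), cfgs,
                                    seed=19000 + 13 * a)
            coefs.append(stay_regression_interaction(df))
        mean, se = np.mean(coefs), np.std(coefs) / np.sqrt(len(coefs))
        assert abs(mean) > 2 * se

    def test_too_few_rare_trials_raise(self):
        df = _stochastic_frame([0.0] * 12)  # all common transitions
        with pytest.raises(ValueError):
            stay_regression_rare(df)

    def test_first_trial_of_each_block_excluded(self):
        from twostage.measures import _stay_design

        df = pd.concat([_stochastic_frame([0.0] * 10),
                        _stochastic_frame([0.0] * 10).assign(block_id=1)],
                       ignore_index=True)
        assert len(_stay_design(df)) == 18  # (10 - 1) per block


class TestCursorMeasure:
    def test_midline_crossings_score_zero(self):
        df = _stochastic_frame([0.0] * 10)
        assert cursor_structure_measure(df) == pytest.approx(0.0)

    def test_sign_convention(self):
        # choice 0 commonly -> state 1 (right); crossing +150 is correct
        df = _stochastic_frame([150.0], common_map=(1, 0))
        assert cursor_structure_measure(df) == pytest.approx(150.0)
        # same crossing when the correct state is left scores -150
        df = _stochastic_frame([150.0], common_map=(0, 1))
        assert cursor_structure_measure(df) == pytest.approx(-150.0)

    def test_flipping_sides_negates_measure_exactly(self, rng):
        cfg = TaskConfig(TransitionSpec.stochastic(0.8), n_trials=100)
        df = make_subject_frame(AgentParams(0.7, 0.1, 0.3), [cfg], seed=23,
                                mouse=MouseParams())
        flipped = df.assign(crossing_x=-df["crossing_x"])
        assert cursor_structure_measure(flipped) == pytest.approx(
            -cursor_structure_measure(df)
        )

    def test_binary_variant_bounded(self):
        df = _stochastic_frame([120.0, -30.0, 40.0, 0.0], common_map=(1, 0))
        frac = cursor_structure_measure(df, binary=True)
        assert frac == pytest.approx((1 + 0 + 1 + 0.5) / 4)

    def test_deterministic_warmup_excluded(self):
        cfg = TaskConfig(TransitionSpec.deterministic(4), n_trials=50)
        df = make_subject_frame(AgentParams(0.7, 0.1, 0.5), [cfg], seed=29,
                                mouse=MouseParams())
        side = correct_side(df)
        assert (side[:2] == -1).all() and (side[2:] >= 0).all()
        signed = cursor_structure_measure(df, per_trial=True)
        assert len(signed) == 48


class TestCurves:
    def test_trial_bins_cover_first_40_trials(self, rng):
        cfg = TaskConfig(TransitionSpec.stochastic(0.8), n_trials=100)
        df = make_subject_frame(AgentParams(0.7, 0.1, 0.3), [cfg], seed=31,
                                mouse=MouseParams())
        df = append_beliefs(df)
        curves = binned_curves(df)
        assert list(curves["trial_bin"]) == list(range(8))
        assert curves["trial_lo"].iloc[0] == 1 and curves["trial_hi"].iloc[-1] == 40

    def test_higher_p_reaches_higher_asymptotic_belief(self):
        frames = []
        for i, p in enumerate((0.6, 0.9)):
            cfg = TaskConfig(TransitionSpec.stochastic(p), n_trials=100)
            for a in range(15):
                f = make_subject_frame(AgentParams(0.7, 0.1, 0.0), [cfg],
                                       seed=3300 + 7 * a + i, subject_id=a)
                # belief toward the *common* side of the chosen option
                f = append_beliefs(f)
                common = np.where(f["is_common"].astype(bool), f["state"],
                                  1 - f["state"])
                f["belief_right"] = np.where(common == 1, f["belief_right"],
                                             1 - f["belief_right"])
                frames.append(f.assign(block_id=i))
        curves = binned_curves(pd.concat(frames, ignore_index=True),
                               value_cols=("belief_right",))
        last = curves[curves["trial_bin"] == 7].set_index("param")
        assert last.loc[0.9, "belief_right"] > last.loc[0.6, "belief_right"]

    def test_belief_distance_curve_monotone(self, rng):
        cfgs = [TaskConfig(TransitionSpec.stochastic(p), n_trials=100)
                for p in (0.6, 0.7, 0.8, 0.9)]
        frames = [
            append_beliefs(make_subject_frame(
                AgentParams(0.7, 0.1, 0.3), cfgs, seed=4100 + a, subject_id=a,
                mouse=MouseParams(noise_sd=10.0)))
            for a in range(10)
        ]
        df = pd.concat(frames, ignore_index=True)
        df["param"] = 0.0  # pool conditions into one curve
        curve = belief_distance_curve(df)
        big = curve[curve["n"] >= 30]
        assert (np.diff(big["crossing_x"]) > 0).all()


class TestCohortStatistics:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 1.0, 4.0, 3.0]})
        corr, tests = cohort_statistics(df)
        row = corr[(corr["x"] == "a") & (corr["y"] == "a")].iloc[0]
        assert row["r"] == 1.0

    def test_independent_measures_uncorrelated(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        corr, _ = cohort_statistics(df)
        row = corr[(corr["x"] == "a") & (corr["y"] == "b")].iloc[0]
        assert abs(row["r"]) < 0.1 and row["df"] == 498

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        corr, _ = cohort_statistics(df)
        row = corr[(corr["x"] == "a") & (corr["y"] == "b")].iloc[0]
        assert np.isnan(row["r"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cohort_statistics(pd.DataFrame({"a": [1.0, 2.0]}))


def test_subject_measures_table():
    cfgs = [TaskConfig(TransitionSpec.stochastic(p), n_trials=100)
            for p in (0.7, 0.8)] + [
        TaskConfig(TransitionSpec.deterministic(4), n_trials=100)]
    frames = [make_subject_frame(AgentParams(0.7, 0.1, 0.5), cfgs,
                                 seed=5100 + a, subject_id=a,
                                 mouse=MouseParams())
              for a in range(3)]
    table = subject_measures(pd.concat(frames, ignore_index=True))
    assert len(table) == 3
    for col in ("reward_rate_stochastic", "reward_rate_deterministic",
                "cursor_stochastic", "stay_slope_rare", "interaction_coef"):
        assert col in table.columns and table[col].notna().all()
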