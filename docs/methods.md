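# Methods

## Task generative model

Each block is 100 trials (configurable). The two second-stage states pay
independent bounded Gaussian random walks: the mean takes a step
`N(0, drift_sd)` per trial and is clipped to `[0, 100]`; the realized
reward adds `N(0, noise_sd)` and is clipped again. Defaults
`drift_sd = noise_sd = 20` points. Clipping (rather than reflection) is the
default boundary rule; reflection is available via
`RewardWalkParams(boundary="reflect")`. Initial means are drawn uniformly
on the bounds per state. With these settings the walks spend appreciable
time near the bounds, which makes learning rates below 1 optimal and keeps
the two states' values well separated much of the time.

**Stochastic condition.** Option `a` reaches its common state with
probability `p_common ∈ (0.5, 1]`; the mapping is reversed for the other
option. The side pairing (`common_map`) is counterbalanced across blocks by
a seeded coin flip in the cohort generator.

**Deterministic condition.** The second-stage state on trial `t` is a
deterministic function of the last three first-stage choices through four
history classes — SSS (three repeats), ALT (alternation), S1 (repeat of one
back only), D12 (current differs from the two equal lags) — each mapped by
a pattern table to `stay` or `switch` relative to the previous trial's
state. A second dialect (`absolute_state`) maps history classes directly to
states. Built-in pattern 4 uses the absolute dialect: repetition histories
(SSS, S1) lead to the left state, alternation histories (ALT, D12) to the
right, so repeating one option always yields the left fractal and constant
alternation always yields the right one. Patterns 1–3 are **synthetic
stand-ins**: their exact experimental tables are not published in the text
this design follows, so the package ships three non-trivial stay/switch
tables chosen once so that the pattern set as a whole reproduces the
documented incentive structure — a purely model-free agent earns the
schedule average (measured +0.06 ± 0.09 points/trial at α = 0.7, β = 0.1,
400 agents) while a purely model-based agent earns far more
(+7.5 points/trial). Any custom `PatternTable` can be substituted.

**Warm-up rule.** The first two trials of a deterministic block (no full
three-choice history) draw the state uniformly at random; the pattern
applies from trial 3 on. The model-based value during warm-up falls back to
the unweighted mean of the two cached state values, and warm-up trials are
excluded from the cursor structure measure (no defined correct side).

## Agent

Values initialize at 50 (the reward-range midpoint) at each block start.
The per-trial order is: form `q^MB` and `q^HYB` from the previous trial's
cached values → choose → observe transition and reward → update the reached
state's `v` (Rescorla-Wagner) and the chosen option's `q^MF`. The TD(λ)
first-stage target is `λ·r + (1−λ)·v(reached state)`, with `v` taken
*before* its own update that trial; `λ = 1` reduces exactly to the TD(1)
update and `λ = 0` to TD(0). `β` is a multiplicative sensitivity on the
Q-difference (an inverse-temperature role): on the 0–100 point scale,
realistic fitted values are of order 0.1. Perseverance enters the logit as
`ρ · (±1)` for the previous choice. The simulated agent is endowed with the
true transition structure (probabilities or pattern), matching the model
used for estimation; agents that *learn* the transition structure are out
of scope.

## Beliefs and cursor generation

A Beta-Bernoulli ideal observer tracks, independently per option (prior
Beta(1,1); a coupled/mirrored variant is available), the posterior
probability that the option leads to the right-hand state; the posterior
mean is the pseudo-count fraction. The synthetic cursor crossing is

```
x = gain · (belief_right − 0.5) + N(0, noise_sd)      [pixels from midline]
```

with defaults `gain = 500` px per unit belief (belief 0.9 → ≈ 200 px) and
`noise_sd = 50` px, chosen once as plausible screen-scale magnitudes for a
1920-px display with the reveal line at 70% of screen height. In
deterministic blocks the observer's belief is the pattern's prediction
(0.5 during warm-up). By default the cursor is driven by the observer's
beliefs *regardless of the agent's `w`* — structure knowledge and
model-based choice are generatively independent, which is the dissociation
the synthetic cohorts exist to exercise; set `cursor_mode="none"` (or drive
it from a custom belief) to change this. No transient post-rare-transition
belief dampening is modeled.

## Fitting

`(α, β, w)` (plus `λ`, `ρ` for the variants) are estimated per 100-trial
block by bounded maximum likelihood: `α, w, λ ∈ [0, 1]`, `β ∈ [0, 10]`,
`ρ ∈ [−5, 5]`, best of 10 Latin-hypercube multi-starts (the `β` axis is
warped toward small values, where fitted values live), L-BFGS-B, fully
deterministic given the seed. BIC = `2·nll + k·ln(n)`. The likelihood
kernel is an exact forward replay of the agent's update order; it is
verified against an independently written literal trial-loop oracle to
1e-10.

**Identifiability of `w`.** A block cannot constrain `w` when model-based
and model-free value differences are collinear or the model-based
difference is constant (e.g. both state values pinned at the
initialization). A block is flagged non-identified when
`|corr(Δq^MB, Δq^MF)| > 0.999` (or `Δq^MB` is constant), or when the
profile likelihood over a 21-point `w` grid — re-optimizing the nuisance
parameters at each point, warm-started by continuation *and* from the best
fit (the continuation path alone can get trapped on the flat `β = 0`
plateau) — spans less than 0.01 nats. Flagged blocks are excluded from
subject-level `w` averages. This rule is an operational stand-in for an
exclusion criterion that the source experiment did not publish; thresholds
are configurable.

## Measures

* **Normalized reward rate**: points earned minus the within-block average
  of the two states' realized schedules (removing schedule luck); zero for
  any chooser that tracks the schedule average.
* **Stay regressions**: per-subject penalized logistic fits (L2 strength
  1e-4 as a separation guard — rare-transition subsets at p = 0.9 can
  separate) of stay on the previous reward, either restricted to
  rare-transition trials or with a reward × transition-type interaction
  (transition coded ±0.5). The first trial of each block has no stay value
  and is excluded. Rewards enter in raw points, so slopes are comparable
  across simulations. Per-subject fixed-effect fits aggregated by t-tests
  replace mixed-effects estimation, deliberately keeping the dependency
  surface small.
* **Cursor structure measure**: mean signed pixel distance of the line
  crossing toward the correct side (common state in stochastic blocks,
  pattern prediction in deterministic blocks). Flipping every crossing's
  side negates it exactly; a binary fraction-correct variant exists.
* **Learning curves**: beliefs and crossings averaged over the first 40
  trials in bins of 5, and crossing distance per belief bin of width 0.1.

## Synthetic cohorts and recovery

Default design: 57 subjects × 8 blocks (stochastic p = 0.6/0.7/0.8/0.9 and
patterns 1–4) × 100 trials, randomized block order, counterbalanced
mappings. Per-subject parameters: `α ~ Beta(3.5, 1.5)` (median ≈ 0.72),
`β ~ LogNormal(ln 0.1, 0.5)` (median 0.1), `w ~ Uniform(0, 1)` — medians
chosen to mirror typical fitted values, without claiming the empirical
distributions. Everything descends from one `master_seed` through
`SeedSequence` spawning. `recovery_experiment` refits every block and
reports per-parameter true-vs-recovered Pearson r, bias, RMSE, and the
non-identified fraction: at β = 0.3 and 800 stochastic trials per subject,
`w` recovery reaches r ≈ 0.95; at the default heterogeneous β
(median 0.1), recovery of `w` is weaker and `α` weaker still — estimation
noise at realistic sensitivities is itself a finding the cohorts reproduce.

## Numerical choices

Log-likelihoods use the stable `log1p(exp(−|z|))` form. The profile and
multi-start optimizations clip proposals to the parameter box before
evaluation. Degenerate inputs (blocks under 20 trials, all-stay subsets,
zero-variance measures) raise or flag rather than silently produce numbers.

## Known limitations and measured deviations from the idealized claims

The synthetic data contain no reaction times, trajectory curvature, ITIs,
belief forgetting, or post-rare-transition belief resetting; cursor noise
is Gaussian and homoscedastic. Pattern tables 1–3 are stand-ins (above).
Two idealized claims about this task measurably do not hold exactly under
the standard hybrid model, and the package reports the honest values:

* **The stay-slope sign change is above w = 0.5.** After a rare transition
  with reward `r`, the model-based logit change for staying is
  `−β(2p−1)·α(r − v_s)` while the model-free change is `+β·α(r − q^MF)`;
  the model-based effect carries the factor `2p − 1`, so at p = 0.7 the
  mixture's rare-trial slope crosses zero near w ≈ 0.64 (β = 0.1; ≈ 0.55
  in the β → 0 limit, ≈ 0.55 at p = 0.9), approaching 0.5 only as p → 1.
  The often-quoted "slope = 0 at w = 0.5" is exact only in that limit.
* **A pure model-free agent has a small positive reward × transition
  interaction** (≈ +0.006 logit per point, ~10% of the main reward
  effect): the reward walks are autocorrelated, so after a *common*
  transition the previous reward correlates with the chosen option's
  cached value, inflating the common-trial stay slope. The common/rare
  stay curves of a model-free agent coincide only approximately.
* **Model-based choice is weakly payoff-relevant even at 400 stochastic
  trials**: the per-trial advantage (~1.5 points at β ≈ 0.1) makes
  r(w, reward rate) across a 57-agent cohort with `w ~ U(0, 1)` hover at
  the detection threshold (r ≈ 0.2–0.3), becoming reliably significant
  only with thousands of trials per agent (r ≈ 0.7 at 5000).
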