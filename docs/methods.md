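# Methods

`woolsim` simulates a lameness-spotting serious game — a virtual sheep flock
observed by virtual players — and implements the statistical pipeline used to
evaluate cohorts of players.  This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic data can and
cannot tell you about real players.

## Flock behaviour model

Each sheep is an independent semi-Markov process over three behaviour states
(graze, stand, walk).  Bout durations are exponential with state-specific
means; at bout expiry the next state is drawn independently of the current
state with probability

    P(enter state j) ∝ budget_j / mean_bout_j.

Self-transitions are allowed: re-entering the current state simply begins a
new bout of the same behaviour (observationally a longer dwell).  This rule
was chosen because, by renewal–reward, the long-run occupancy of state *j*
is proportional to `entry_probability_j × mean_bout_j ∝ budget_j`, so the
stationary time budget equals the configured budget **exactly**, for every
configuration.  The more obvious alternative — forbidding self-transitions
and renormalizing the entry weights over the other two states — does not
have this property: its embedded chain has stationary distribution
`π_i ∝ w_i (W − w_i)` (with `w_i = budget_i / mean_bout_i`, `W = Σ w`),
which at the default parameters would distort the budgets to roughly
65/29/6 instead of 73/23.5/3.5.  Indeed no zero-diagonal chain can produce
the required entry distribution at the defaults, because the grazing state's
entry share `w_graze / W ≈ 0.52` exceeds ½.  A useful corollary of the
chosen rule is that bout state sequences are i.i.d., which makes long-horizon
occupancy simulation (`empirical_occupancy`) trivially vectorizable.

Defaults: budgets 0.73 / 0.235 / 0.035 (grazing / standing / walking, the
game's activity budget, consistent with real ovine activity budgets in which
walking is a small minority of time); mean bouts 60 / 30 / 10 s (graze bouts
long, walk bouts brief — walking is a short window of opportunity); flock of
24; 600 s sessions; per-sheep lameness probability 0.5.

**Time stepping.**  The engine advances on a 1 s tick.  Bout clocks are
continuous: a tick subtracts `tick` from the remaining bout and, on expiry,
the *negative remainder carries into the next bout*, so the state at tick
boundaries is exactly the state of the underlying continuous-time process
sampled on a grid.  Occupancy measured at ticks is therefore unbiased; no
quantization correction is needed.  Several transitions may fall within one
tick (they are logged in order with equal timestamps).

**Initialization.**  The initial state is drawn from the stationary
occupancy (the budgets) and the initial bout remaining from the stationary
residual-life distribution — which for exponential bouts is the same
exponential, by memorylessness.  The process is therefore stationary from
t = 0 and needs no burn-in.

**Lameness.**  Status is Bernoulli(p_lame) per sheep at initialization
(coin-flip assignment, so the *expected* lame fraction is 50% but the count
varies binomially) and immutable for the session.  Lame sheep carry the
early-lameness cue triple — shortened stride on one uniformly chosen leg,
quickened opposite stride, head nod — corresponding to a locomotion-score-2
presentation.  The affected leg is logged but does not alter detection in
the default observer; it is a hook for finer-grained observer models.

## Observer model

The virtual player is a per-bout signal-detection classifier.  It holds
`attention` sheep in view, relocating every `relocate_period` s to the
unmarked sheep observed least recently (ties by id) — a stand-in for the
systematic scanning strategies players report, without modelling 2-D space.
When a sheep in view completes a walking bout that was in view from start to
finish, the player makes exactly one Bernoulli judgement: mark with
probability `sensitivity` if the sheep is lame, `false_alarm` if healthy.
Partial glimpses yield no judgement (brief, partially seen walks are not
enough to judge a gait).  Marks are irreversible and a sheep is judged at
most once per bout.  Players quit at `quit_time` or at the 10-minute timer.

Shipped defaults: sensitivity 0.95, false alarm 0.02, attention 24 (whole
flock in view), relocate period 15 s.  The sensitivity default was fixed
once by grid search against the time-played calibration below and is not
re-fit at runtime.

**Time-played calibration and its ceiling.**  Regressing each simulated
player's count of correctly marked lame sheep on minutes played (quit times
uniform on 1.45–10 min) gives a slope of ≈ 0.8 sheep per additional minute
at the shipped defaults.  This is a structural ceiling, not a tuning
failure: under passive observation a fully watched sheep presents walking
bouts as a Poisson stream at rate `budget_walk / mean_bout_walk ≈ 0.21 per
minute`, so the expected hit count follows the saturating curve
`E[hits | t] = n_lame (1 − e^{−λt})` with `λ = sensitivity × 0.21/min`.
Over t ∈ [1.45, 10] the ordinary-least-squares slope of this family is at
most ≈ 0.82 sheep/min, for **any** λ, with an expected 12 lame sheep; even
an arbitrary monotone curve bounded by 12 cannot exceed ≈ 2.1 (the step-
function limit).  Field reports of steeper observational slopes in human
players therefore cannot arise from a constant-skill passive observer; they
would require behavioural heterogeneity (e.g. skill correlated with
persistence) that this model deliberately does not build in.  Questionnaire
covariates are carried on each participant record but have no mechanistic
effect by default, mirroring the absence of experience effects in evaluation
cohorts; the synthetic-cohort module can couple them to sensitivity for
power studies.

## Scoring

In-game "accuracy" is precision — the percentage of marked sheep that are
truly lame — and is undefined (NA, excluded from analyses) when no sheep was
marked; no 0/0 convention is invented.  Recall is the percentage of truly
lame sheep marked; it is undefined only for the degenerate draw of a flock
with zero lame sheep (a warning is emitted).  Scores are stored at full
precision; display rounding is one decimal place and configurable.  Marking
every sheep ("shotgun" play) forces recall to 100 while accuracy collapses
to the lame prevalence — the signature used to screen for cheating.

## Statistical pipeline

* **Transform.**  Accuracy and recall are percentages, so they are arcsine
  square-root transformed (`asin √(p/100)`) before testing and modelling.
* **Normality/skewness.**  D'Agostino's skewness test: sample skewness
  `g1 = m3 / m2^{3/2}`, standardized with its exact small-sample moments and
  mapped through the Johnson SU transformation to an approximately normal z,
  two-sided p.  Valid for 8 < n < 46340.  The implementation delegates to
  `scipy.stats.skewtest` (the same standardization used by R's
  `moments::agostino.test`), with one correction: at exactly zero sample
  skewness scipy substitutes y = 1 into the transformation, producing a
  spurious nonzero z, so that case returns z = 0, p = 1 as the formulas
  dictate.  A unit test cross-checks z against a direct evaluation of the
  published formulas.
* **Power.**  The detectable Cohen's f² for the overall F(u, v) test is the
  root of `P(F′(u, v, ncp) > F_crit(1−α)) = power` with the noncentrality
  convention `ncp = f²·(u + v + 1)` (the convention of the standard power
  routines for linear models; required to reproduce f² = 0.21 at u = 1,
  v = 61, α = 0.05, power = 0.95).  Solved by Brent bracketing on
  (0, 1000] to a power error below 1e−8.
* **Models.**  Candidate explanations are tested as single-predictor OLS
  models of transformed recall, in a fixed, pre-declared order (the package
  takes an explicit plan; it does not automate the exploratory
  pick-the-visually-strongest step, which is not an algorithm).  A
  categorical predictor with k levels contributes k−1 numerator df.
* **Sequential Bonferroni.**  The k-th model's p-value is multiplied by k
  (the count of models tested so far, capped at 1); testing stops at the
  first model whose corrected p falls below α ("correct, then stop").  The
  multiplier-k reading is adopted because a multiplier of k−1 would leave
  the first p-value uncorrectable.  Note a property of this scheme worth
  knowing: it is *not* a familywise-error-controlling procedure.  Model k
  rejects when `p_k < α/k`, so with m independent null models the
  familywise error rate is `≈ 1 − Π(1 − α/k) ≈ α·H_m` (about 0.10 for
  m = 4 at α = 0.05), twice the nominal level.  The package implements the
  scheme as stated rather than silently substituting Holm or classical
  Bonferroni.
* **Contingency test.**  Pearson chi-squared without continuity correction;
  df = (r−1)(c−1) (8 for the nine-signs-by-experience table).
* **Group summaries.**  Mean, linear-interpolation quartiles, and a
  Student-t 95% CI of the mean (group sizes are small).  A group mean is
  flagged a *poor estimate* when the lower quartile falls strictly below
  the lower CI limit or the upper quartile strictly above the upper limit.
* **Likert.**  Row-normalized negative/neutral/positive percentages;
  summarization only.

## Synthetic cohorts

The generator emulates the cohort structure of a 63-participant evaluation
study: farming experience Bernoulli(0.5) (the observed split was 31/32);
years with sheep log-normal with median 10 among the experienced; perceived
lameness-prevalence band with mode "5–10%"; nine lameness-sign look-for
flags with higher rates among the experienced (0.70 vs 0.45); engagement
covariates uniform over their levels; time played uniform on 1.45–10 min
(only the range is documented for real players; uniformity is an
assumption).  Only the printed facts are treated as targets; every other
marginal is a plausible, overridable default.

Scores come in two modes.  *Mechanistic*: each row's time played becomes the
quit time of a default virtual observer who actually plays the game.
*Statistical*: transformed recall follows `y = β₀ + β₁(x − x̄) + ε` with
`ε ~ N(0, σ²)`, σ = 0.2 rad, β₀ = π/4 (50% recall at the cohort mean), and
β₁ set from the planted effect via `f² = R²/(1 − R²)`, i.e.
`β₁ = √f²·σ/sd(x)`; the result is back-transformed to percent and clamped to
[0, 100], with a warning if more than 5% of rows clamp (at the defaults
clamping is ~0.1%).  σ = 0.2 was chosen once so that back-transformed recall
spans most of the percentage range, as real cohorts' recall does, while
keeping clamping negligible.  Accuracy in statistical mode is drawn
Beta(8, 2)-scaled — high and negatively skewed, the signature of honest
play.

What passing tests on these cohorts show: the pipeline's operating
characteristics (type-I error, power at the designed effect size, parameter
recovery) under its own assumptions.  What they do not show: anything about
real players — the generator has no skill–persistence correlation, no
question-wording effects, no self-report error in scores, and its covariates
are independent of recall by construction unless an effect is planted.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and the reproduction script are
chosen so Monte-Carlo error sits well inside each tolerance: occupancy uses
10,000 simulated minutes × 20 flocks (≈ 4.8 M agent-minutes; SE ≲ 0.03
percentage points); lameness assignment uses 10,000 seeded flocks (SE ≈
0.1 pp); the calibration regression uses 2,000 simulated players; pipeline
error rates use 400 (null) and 2,000 (planted) generated cohorts.  All
randomness flows from `numpy.random.Generator` streams spawned from a single
seed; identical seeds give byte-identical session logs and cohort tables.
Ties in view relocation break by sheep id; event timestamps within a tick
are equal and logged in processing order.

## Known limitations

* No spatial layout, sheep-driving ("working the flock"), sheepdog, sound
  feedback, or fatigue dynamics; observation is purely passive, which is
  precisely why detection saturates with time.
* The default observer's covariates are inert; null findings for experience
  in synthetic cohorts are built in, not emergent.
* Exponential bout durations are the simplest choice consistent with the
  stated budgets; real bout-length distributions are heavier-tailed.
* The sequential multiple-testing scheme inflates familywise error (see
  above); use the reported raw p-values if strict control matters.
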