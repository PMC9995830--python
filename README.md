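# woolsim

Early lameness in sheep — typically caused by bacterial foot infections — is
first spotted by eye, from subtle gait changes: a shortened stride on the
affected leg, a quickened opposite stride, a nodding head.  Serious games
that ask players to find the lame sheep in a virtual flock are one way to
assess and train this skill.  `woolsim` is a headless, fully seeded
simulator of such a game, plus the statistics used to evaluate player
cohorts.  It is aimed at researchers in livestock-welfare education and
serious-games evaluation who want to prototype game mechanics, run power
studies, or re-analyse cohort data without a 3-D client.

The package has three layers:

* **Flock engine** — each of 24 sheep is a semi-Markov process over
  graze/stand/walk with exponential bouts; next states are sampled with
  probability ∝ `budget/mean_bout`, which makes the stationary activity
  budget equal the configured 73% / 23.5% / 3.5% exactly.  Lameness is
  assigned per sheep by a coin flip (p = 0.5) at session start and expressed
  as gait cues while walking.
* **Virtual observers** — per-bout signal detection: a sheep that completes
  a fully watched walking bout is marked with probability `sensitivity`
  (lame) or `false_alarm` (healthy).  Sessions are scored by in-game
  *accuracy* (precision: % of marked sheep truly lame) and *recall* (% of
  lame sheep marked), with the time remaining on the 10-minute clock.
* **Study statistics** — arcsine-square-root transforms, D'Agostino's
  skewness test, detectable-effect-size solving from the noncentral-F
  power function (`ncp = f²(u+v+1)`), single-predictor OLS models tested in
  sequence with sequential Bonferroni correction and a stop-at-first-
  feasible rule, chi-squared contingency tests, and group summaries with a
  small-sample quality flag — plus a synthetic participant-cohort generator
  (mechanistic or statistical, with a plantable Cohen's f²).

## Worked example

Solve the post-hoc power analysis for a 63-participant cohort (1 on 61
degrees of freedom, 5% significance, 95% power):

```console
$ woolsim power --v 61
{"u": 1, "v": 61, "alpha": 0.05, "power": 0.95, "f2": 0.2129860399383353}
```

f² ≈ 0.21 is the smallest ("medium-to-large") effect such a cohort can
reliably detect with a single-predictor linear model.

Simulate one virtual player with the shipped default observer:

```console
$ woolsim player --seed 3
participant_id,farming_experience,years_with_sheep,...,time_played,accuracy,recall
1,FALSE,NA,...,10.0,100.0,69.23076923076923
```

This player watched the flock for the full 10 minutes, marked only truly
lame sheep (accuracy 100%), and found 9 of the 13 lame sheep that this
seed's coin flips produced (recall 69.2%) — high precision with partial
recall is the signature of honest, passive observation, since detections
are rate-limited by how often sheep choose to walk.

The same works in Python, end to end:

```python
from woolsim import EffectSpec, generate_cohort, run_study_pipeline

cohort = generate_cohort(EffectSpec(planted_f2=0.21, seed=1))  # 63 players
report = run_study_pipeline(cohort, [("recall", "farming_experience"),
                                     ("recall", "time_played")])
print(round(report.power.f2, 2))          # 0.21
print(report.feasible_model)              # e.g. "time_played"
```

Other subcommands: `woolsim simulate` (unobserved session → JSON-lines event
log), `woolsim score --log ...`, `woolsim cohort` (synthetic cohort CSV),
`woolsim analyze --cohort ...` (full pipeline report on any cohort CSV in
the documented schema, including exported real-study data).  Every run
writes a JSON manifest with seeds and config hash.

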