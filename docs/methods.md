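# Methods

## The competition model

stepduel simulates a cumulative step-count competition between one human
user and a field of NPC rivals, updated once per calendar day. The design
goal is control over the *psychological content* of the presented
information, so rivals are not agents: the engine decides the user's rank
from their measured effort and then constructs every rival's score by
placement formulas around the user's score. The user's own score is always
the accumulated truth — `initial_score + Σ measured daily steps` — only the
context around it is synthetic.

### Effort and baseline

Daily effort is `E = steps_today − baseline`. The baseline is the rounded
mean of the last `baseline_window` days (default 7) of pre-game logs, and is
frozen at game start: a rolling baseline would make effort self-referential
(raising your steps would raise the bar for tomorrow's effort), whereas the
frozen baseline keeps effort interpretable as deviation from the user's
pre-intervention habit. Timestamps are not modelled; one update per calendar
day. A day missing from a replayed log is imputed at the baseline (zero
effort) with a warning — a neutral choice that creates no spurious rank
events.

### Rank fluctuation

The rank moves by `k = int(E / threshold)` with `int()` truncating toward
zero, so −1500 steps against a 1000-step threshold costs one rank, not two;
truncation also makes `k` odd-symmetric in `E`. The convention lives
entirely in `rank_delta`, so switching to floor semantics would be a
one-line change. At exact multiples the formula wins: `E = threshold` earns
the rank unit. Each unit moves the user past the adjacent rival, who shifts
one place in compensation; movement clamps at rank 1 and at the bottom of
the field.

Top-of-field rule: a leader keeps 1st place only while daily effort clears
the rank-up threshold; otherwise the rank drops (to 2nd at minimum), so a
rival able to provide rank fluctuations is above the user again. The bottom
edge has no analogous forced promotion: a last-placed user simply cannot
fall further. The asymmetry is deliberate — the design needs headroom for
rank-up events, not for rank-down ones.

### Score gaps

The gap to the rival `n` ranks away (`n > 0` above the user) is

    gap(n) = BD|n| + EffortFactor(n) + RandomFactor(n)

* `BD|n| = bd_coefficient × |n|` — linear spread, so "there is always a
  rival about `bd_coefficient` steps away".
* `EffortFactor(n) = −sign(E)·sign(n) × BD|n| × m × frac(|E|/threshold)`,
  `0 < m < 1`, default 0.3. The fractional part is taken of `|E|` with the
  sign carried separately (the fractional part of a negative ratio is
  otherwise ill-defined). The signed value adjusts the gap *magnitude*:
  positive effort shrinks gaps to rivals above and grows gaps to rivals
  below, which is exactly the "progress is visible even without a rank
  change" mechanism. The factor applies to all rivals, since it is indexed
  by `n`.
* `RandomFactor(n) = ±(BD|n| × l)` with `l ~ U[0, l_max]`, default
  `l_max = 0.2` — small plausibility noise, bounded by `l_max × BD|n|`.

Numerical conventions: each factor is rounded to the nearest whole step and
scores are integers; the total gap is floored at 1 step; and per side the
gaps are forced strictly increasing in `|n|` (a violating gap is bumped to
one step above its inner neighbour), so scores can never tie or invert
relative to ranks even under extreme `m`/`l_max` settings. Under the default
parameters the raw formulas already satisfy the ordering (the worst case
`|n|+1` gap exceeds the best case `|n|` gap whenever `m·frac < 4/3`), so the
repair is a guard, not an active ingredient. Rival cumulative scores may
decrease day-over-day as a side effect of gap placement; nothing constrains
NPC plausibility and the formulas are applied exactly.

Determinism: each game owns a seeded `numpy` PCG64 stream. Per day the
engine draws one vector of gap multipliers and one vector of signs, over
rivals in ascending rank order; the stream state is serialised into the JSON
snapshot, so replaying a log or resuming from a snapshot is bit-identical.

### Two Main parameterisations

| condition | threshold (steps) | bd_coefficient (steps) | field | initial rank / score |
|-----------|------------------|------------------------|-------|----------------------|
| Main 1    | 1000             | 1000                   | Sub 1: 10, Sub 2: 100 | 6 / 35,000 (Sub 1); 66 / 300,000 (Sub 2) |
| Main 2    | 8000             | 8000                   | same  | same |

Initial scores are independent config values (the printed "about 35,000" /
"about 300,000" figures imply a ~6000 steps/day accumulation history that is
not otherwise reconciled with measured baselines, so no relation is
enforced). NPC day-0 scores are placed by the same gap formulas at zero
effort.

## Grouping

Fields larger than the group size are partitioned into contiguous-rank
blocks (default 10): group *g* covers ranks `(g−1)·10+1 … g·10`, the last
group possibly undersized. Grouping is purely positional — no score
clustering — and is recomputed at every update, which automatically yields
the boundary semantics: a player crosses into a better group exactly when
their overall rank crosses a multiple of the group size (rank 41 → 40
promotes from group 5 to group 4), and the displaced boundary player is
demoted in compensation. Promotion/demotion events are emitted for logging.

## Presentation

The daily payload has a comment part (current rank, signed rank change
versus the previous day, gaps to the adjacent rivals) and a ranking part
(rank, display name, score for each player of every visible view). Views by
condition: Sub 1 sees its 10-player field; Main1-Sub2 sees both its
10-player group and the 100-player board; Main2-Sub2 sees only the
100-player board. Where a group view is visible it is the *primary* view —
the comment's gap figures refer to it — since steering attention to the
close field is that condition's mechanism; otherwise the overall board is
primary. Every number in the comment is recomputed from the ranking rows, so
the two parts cannot disagree. Comment wording is template-overridable; NPC
nicknames are generated deterministically from the game seed. A plain-text
notification digest (≤1000 characters, ranking window centred on the user)
stands in for the original messaging-app transport, which is out of scope.

## Synthetic participants and the study harness

`generate_cohort` draws personal baselines from a lognormal with median
8000 steps/day and log-sd 0.25 (typical adult pedometer means and
between-person spread), day-to-day noise sd 1500 steps (within-person
variability of daily totals), and transtheoretical-model motivation stages
1–5 from a geometric-family categorical solved to hit a target cohort mean
(default 2.2, a contemplation-heavy, low-motivation cohort). The study runs
three simulated periods of 14 days (pre, intervention, post) over 42
participants in four cells; the device-habituation period has no
computational content and is not simulated.

`balance_assign` randomises participants into the four cells under balance
constraints (default: cell mean baselines within 500 steps, mean stages
within 0.5) by randomised local search — random equal-size start, then
pairwise swaps accepted when they reduce the tolerance-scaled spread, with
random restarts. This reliably satisfies both tolerances where one-pass
dealing does not, while remaining randomised across the many valid
assignments. Infeasible tolerances raise after the retry budget.

### The behavioural response model

Daily steps are `round(max(0, Normal(μ_i + r·s_{t−1}, σ_i)))` where `r` is
the participant's responsiveness (steps per unit of feedback) and `s_{t−1}`
the previous day's feedback signal, non-zero only during the intervention:
+1/0/−1 for a rank that rose/held/fell, plus a +1 closeness bonus when a
rival sits within 1000 steps above the user. The closeness cutoff is an
absolute step distance, not a multiple of the condition's own gap scale: a
relative cutoff would fire equally often under both parameterisations by
construction (the realised gap is the scale plus symmetric noise), whereas a
close rival is a fixed psychological notion — a rival ~8000 steps ahead is
not "close". With the absolute cutoff the promoting parameterisation emits
positive feedback routinely (mean daily signal ≈ 0.5–0.6 at moderate
responsiveness) and the withholding one essentially never, which is the
designed contrast.

This response model is invented plumbing: it exists so the engine's full
path (effort → rank → gaps → rendering → next-day behaviour) is exercised
end to end, not as a claim about human behaviour. The default is the null,
`responsiveness = 0`, under which participant steps are exactly independent
of the game (the feedback signal is the only coupling). Consequences worth
noting: it is linear and memoryless, has no saturation, habituation or
day-of-week structure, and no dropout or intentional non-participation —
so passing tests demonstrate the engine's mechanics and the harness's
statistical calibration, not that real cohorts would move by any particular
amount. The original field experiment's ≈1000-step human effect is an
empirical outcome, not an algorithmic property, and is deliberately not a
validation target.

`summarize` reports per-cell per-period means with standard errors and a
standard mixed two-way ANOVA (period within subjects, Main or full condition
between) with Bonferroni-corrected pairwise comparisons, delegated to
pingouin; with zero-variance input it reports F = 0 rather than 0/0. The
responsiveness-recovery check regresses intervention-day steps, centred on
the participant's known generative mean, on the lagged signal. The known
mean is used deliberately: an estimated baseline is endogenous to the loop
(a lucky pre-period inflates the baseline, depresses measured effort and
thus the signal), biasing the slope, while with the known mean the regressor
depends only on past noise and OLS is unbiased — verified over 200 replicate
studies (bias z ≈ −0.8, 93.5% of replicates within 2 standard errors).

## Problem sizes and runtime choices

Property suites run at the scale they are stated: 10⁴ randomised daily
updates for the rank-permutation invariant, 10⁴ seeded draws for the
random-factor bound, 200 random rankings for regroup equivalence, and 200
replicate studies (n = 42, 14-day periods) for recovery. ANOVA power for an
injected +1000-step cell shift is checked over 200 Monte-Carlo replicates of
the summary pipeline. All stochastic tests are seeded.

## Known limitations

* NPC scores may drop day-over-day; an observant user of a real deployment
  would notice. The engine favours exact gap semantics over NPC plausibility.
* The grouping view shows contiguous rank blocks only; score-distance
  clustering and dynamic group sizes are out of scope.
* Multi-human games, real-time (sub-daily) updates and wearable ingestion
  protocols are out of scope.
* The behavioural model's simplicity means harness results quantify the
  engine, not people (see above).
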