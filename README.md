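# exerprog

Personalized progression for motor-cognitive exergame training, plus
the feasibility bookkeeping and nonparametric statistics used to
evaluate such training in small clinical cohorts (e.g. chronic stroke
rehabilitation).

Exergames train motor and cognitive functions simultaneously, but
prescribing them well requires *personalized progression*: task
difficulty should track each patient's ability so that perceived
difficulty stays in a productive band. `exerprog` implements a
complete, testable version of such a system:

- **Adapted Gentile taxonomy** — 9 motor skill categories
  (3 environmental-variability levels x 3 action-function levels), each
  split into 4 cognitive domains: a grid of 36 skill sub-categories
  holding candidate games, with deterministic nearest-neighbour
  substitution for uncovered sub-categories.
- **Position-square progression** — the difficulty state is a 2x2
  window into the grid. After each session the patient rates perceived
  motor and cognitive difficulty on a 0–9 visual analog scale; ratings
  below the target band [4.5, 6.75] move the square up one (soft) or
  two (hard) sub-categories on the corresponding axis, ratings above
  it move it down, with clamping at the grid edges.
- **Dosing and session planning** — Timed-up-and-go stratification
  (> 10 s basic, otherwise advanced), 2 sessions/week for 8 weeks with
  +3 min/week (basic 15 -> 36 min, advanced 24 -> 45 min), and session
  composition as 3-min warm-up, a main part of 60–180 s game blocks
  ordered so difficulty peaks in the final third, and a 3-min
  cool-down.
- **Synthetic cohorts** — a seeded patient model (latent skills, linear
  perceived-difficulty response `vas = clamp(5.625 + g·(demand − skill) + ε, 0, 9)`,
  learning drift, absorbing dropout) that generates full simulated
  trials for testing the whole stack.
- **Trial analysis** — the six-rate feasibility protocol
  (inclusion/adherence/compliance/attrition/motivation/satisfaction
  against pre-registered thresholds), per-session difficulty-trajectory
  summaries, and paired pre/post statistics: median/IQR descriptives,
  Wilcoxon signed-rank test (exact and tie-corrected asymptotic), and
  the effect size r = |z|/√n with the standard small/medium/large
  cut-offs (0.30, 0.50).

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import exerprog as xp

# Feasibility protocol on a trial's bookkeeping counts
counts = xp.FeasibilityCounts(
    screened=23, included=13, dropouts=3,
    offered_sessions=189, attended_sessions=165,
    offered_minutes=4974.0, attended_minutes=4915.0,
    mean_motivation=7.67, mean_satisfaction=7.44,
)
print(xp.feasibility_report(counts).to_text())
```

```
criterion     threshold   data                         outcome  met
-------------------------------------------------------------------
inclusion     >= 50       13/23 participants               57%  yes
adherence     >= 80       165/189 sessions                 87%  yes
compliance    >= 80       4915/4974 min                    99%  yes
attrition     <= 15       3/13 participants                23%  NO
motivation    >= 60       mean VAS 7.67/10                 77%  yes
satisfaction  >= 60       mean VAS 7.44/10                 74%  yes
```

13 of 23 screened patients were included (57%, above the 50%
threshold); 3 of 13 dropped out (23% attrition, *failing* the <= 15%
threshold); every other rate meets its bound.

```python
# One progression step and the next session's plan
square = xp.PositionSquare(3, 0)
nxt = xp.advance(square, xp.RatingPair(motor_vas=2.0, cognitive_vas=5.0))
print(nxt)

grid = xp.build_grid(xp.demo_catalog())
plan = xp.plan_session(nxt, grid, xp.assign_group(12.3), week=1)
for b in plan.blocks[:4]:
    print(b.phase, b.cell, b.duration_s, b.game.game_id)
print("total min:", plan.total_s // 60)
```

```
PositionSquare(anchor_row=3, anchor_col=1)
warmup (3, 1) 180 g-e0-d3-a1-00
main (3, 2) 90 g-e0-d3-a2-00
main (3, 2) 90 g-e0-d3-a2-00
main (4, 1) 90 g-e1-d0-a1-00
total min: 15
```

The motor rating 2.0 fell in the soft-progression zone, so the square
moved one column right; the cognitive rating 5.0 was in the target
zone, so the row stayed. The planned 15-minute basic-group session
(TUG 12.3 s > 10 s) opens with a 3-min warm-up from the square's
top-left cell and tiles the 9-min main part with 90 s blocks of
increasing difficulty.

```python
# Paired pre/post analysis (e.g. TUG seconds before/after training)
sample = xp.PairedSample.from_arrays(
    [9.8, 8.1, 12.0, 7.5, 29.0, 8.2, 6.9, 11.4, 7.8],
    [9.1, 7.0, 10.5, 7.7, 26.0, 7.1, 6.4, 10.9, 7.2],
)
res = xp.wilcoxon_signed_rank(sample, method="exact")
print(res.statistic, res.n_eff, res.z, res.p_value, res.r)
```

```
1.0 9 -2.552 0.0078 0.851
```

T = 1 (the smaller signed rank sum), exact two-sided p = 0.0078, and
effect size r = 0.851 — classified "large" by
`xp.effect_size_class(res.r)`.

## Command line

The `exerprog` console script exposes the same operations:
`validate-catalog`, `plan`, `advance`, `simulate`, `trajectory`,
`feasibility`, `analyze`. For example:

```sh
exerprog advance --row 3 --col 0 --motor 2.0 --cog 5.0
exerprog simulate --seed 7 --out log.csv --counts-out counts.json
exerprog trajectory --log log.csv --out traj.csv
exerprog feasibility --counts counts.json --out report.json
```

Seeded runs are byte-reproducible: the same seed yields identical
output files.

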