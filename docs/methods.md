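# Methods

`exerprog` implements a personalized progression system for
motor-cognitive exergame training, together with the feasibility
protocol and nonparametric analysis used to evaluate such training in
small clinical cohorts. This note documents the model, its parameters,
the design choices that were genuinely open, and the limits of what the
synthetic test harness can show.

## The adapted taxonomy

Gentile's taxonomy of motor learning orders motor skills by
environmental context and action function. The adaptation implemented
here uses three ordered levels per motor axis — inter-trial variability
of the environment (none / partial / full) and action function (body
stability / partial body transport / body transport) — yielding 9 motor
skill categories, each split into four cognitive domains (attention,
executive, memory, visuo-spatial): 36 skill sub-categories in total.

The in-memory layout is a 12 x 3 grid with `row = 4*env + domain` and
`col = action`. This canonical layout is a declared convention: the
taxonomy itself has three independent axes, and any faithful
two-dimensional arrangement must interleave two of them. We place the
environment as the major row key and the cognitive domain as the minor
one, in the fixed order attention -> executive -> memory ->
visuospatial, so that the row index is a single ordered
cognitive/environmental difficulty axis suitable for one-dimensional
progression. An alternative 6 x 6 arrangement (2 x 2 cognitive split
per motor cell) would serve equally; it is not implemented, and the
layout is a fixed convention rather than a configurable option.

Real game catalogs do not cover all 36 sub-categories (memory-domain
games are typically missing). Planning therefore never fails on an
empty cell: it substitutes the non-empty cell at minimal Chebyshev
distance, ties broken by smallest (distance, row, col). The
lexicographic tie-break is deterministic and biased toward smaller
indices, i.e. toward *easier* donors — the conservative choice for a
patient population. Provenance of the donor cell is recorded on every
resolved block.

## Rating zones and progression

Perceived motor and cognitive task difficulty are rated after each
session on a visual analog scale from 0 ("very very easy") to 9 ("very
very difficult"). Following Cognitive Load Theory the protocol targets
the band from "neither easy nor difficult" to "difficult". The scale's
nine verbal anchors are assumed evenly spaced on [0, 9] (spacing
1.125), giving default zone boundaries

| zone | interval | move |
|---|---|---|
| hard progression | [0, 2.25) | +2 |
| soft progression | [2.25, 4.5) | +1 |
| target | [4.5, 6.75] | 0 |
| soft regression | (6.75, 7.875] | -1 |
| hard regression | (7.875, 9] | -2 |

All four boundaries are configurable (`zones.*` in the run config).
The target zone is closed at both ends — a rating exactly on a target
boundary produces no move — and the other zones are half-open
accordingly. The difficulty state is a 2 x 2 "position square" on the
grid; the motor rating moves its anchor column, the cognitive rating
its anchor row, and moves are clamped at the grid edges (participants
demonstrably reach the edges, so clamping rather than erroring is the
only sensible behaviour). One rating pair is collected per session and
applied to the next session.

With 3 grid columns the motor axis has only two anchor positions
(0 and 1); the cognitive axis has eleven. This asymmetry is inherent to
the 3-level motor adaptation, not an implementation artefact.

## Dosing and session composition

Baseline Timed-up-and-go (TUG) above 10 s assigns the basic group,
10 s or less the advanced group. Both train twice weekly for 8 weeks
(16 planned sessions), adding 3 minutes per week: basic 15 -> 36 min,
advanced 24 -> 45 min. Warm-up and cool-down (3 min each) are counted
inside the scheduled minutes — a 15-min session has a 9-min main part,
and the main part spans 9–39 min over all (group, week) pairs.

Warm-up and cool-down games come from the square's top-left cell (its
easiest content). The main part is tiled with blocks of a 90 s quantum
(the midpoint of the permitted 60–180 s block range; configurable), the
final block absorbing any remainder while staying within bounds; when
fewer than three quantum blocks would fit but three minimal blocks do,
a near-equal three-way split is used instead. Blocks are drawn from the
square's other three cells and ordered by non-decreasing difficulty
rank (top-right, bottom-left, bottom-right — the diagonal tie between
one-step-harder cells resolved in favour of the cognitive axis), with
surplus blocks allotted to the easier cells. Sorting rather than
search realizes the required intensity profile deterministically: the
hardest block is always last in the main part, so the difficulty peak
falls in the final third and decreases through the cool-down. Under
the protocol's schedule every main part is a multiple of 180 s, so the
quantum tiling is exact and each of the three cells contributes at
least one block.

## The synthetic cohort model

No participant-level records of adaptive exergame trials are publicly
available, so testing uses a generative patient model. It is a test
harness with analyzable fixed points, not an empirical fit.

Each patient has a latent motor skill on the column-demand scale
([0, 2]) and cognitive skill on the row scale ([0, 11]). A session at
square *s* has demand equal to the square's centre, (col + 0.5,
row + 0.5). Perceived difficulty is linear in the demand–skill
mismatch with additive Gaussian noise, clamped to the scale:

    vas = clamp(c_t + g * (demand - skill) + eps,  0, 9),
    eps ~ N(0, sigma^2)

where `c_t` is the centre of the configured target zone (5.625 under
defaults) and `g` is the rating gain (VAS units per demand unit,
default 1). A perfectly matched task is thus rated mid-target. Optional
learning drift raises both skills by `learning_rate` (default 0.05
demand-units) per attended session, capped at the scale maxima.
Dropout is an absorbing per-session Bernoulli hazard applied before
the session; a dropped patient's remaining sessions stay *offered* but
are not attended, which is exactly how the feasibility bookkeeping
counts attrition against adherence and compliance.

Default cohort scale mirrors a single-site feasibility study: 23
screened, 13 included. Default sampling: skills uniform over the
interior of the demand range (motor [0.2, 1.8], cognitive [0.5, 9.5]);
rating noise sd 1.0 (about one scale anchor); dropout hazard 0.016 per
session, which gives roughly a 3-in-13 chance of dropping out over 16
sessions; motivation and satisfaction drawn around means 7.67 and 7.44
(the published cohort means) with sd 1.2, clamped to [0, 10]; baseline
TUG lognormal around the published cohort median 8.24 s with log-sd
0.35, giving roughly 30% basic-group assignments. One global seed
drives everything; per-patient substreams are keyed by a CRC-32 hash of
the participant id, so changing the cohort size never reshuffles the
other patients' trajectories.

Zero-noise behaviour is fully analyzable and is what the property
tests pin down: a static patient whose skills lie within the demand
range reaches ratings inside the target zone within at most 7 sessions
from any start anchor (the measured worst case over the full
anchor x skill lattice is 6), and stays there — the target zone is a
fixed point of the update. A patient whose effective skill exceeds the
hardest square's demand by more than the target half-width rates every
session below target and pins at the hardest anchor (10, 1) — the
below-target drift seen in practice emerges from the model rather than
being scripted.

What the model does **not** emulate: coupled motor-cognitive learning
(the axes drift independently), fatigue or day-to-day fluctuation,
rating anchoring and drift, partial session attendance (attendance is
all-or-nothing per session), and any physiological, gait or
cognitive-test outcome. Passing tests therefore demonstrate the
correctness and stability of the adaptation machinery under a
plausible patient model — not that real patients converge in six
sessions.

## Feasibility protocol

Six rates with pre-registered thresholds: inclusion =
100·included/screened (>= 50), adherence = 100·attended/offered
sessions (>= 80), compliance = 100·attended/offered minutes (>= 80),
attrition = 100·dropouts/included (<= 15), motivation and satisfaction
= 10·mean VAS on the 0–10 scale (>= 60). Percentages are rounded
half-up to integers before the threshold comparison; this reproduces
published protocol tables (13/23 -> 57, 4915/4974 -> 99, 3/13 -> 23,
7.67 -> 77, 7.44 -> 74). A known reporting discrepancy exists for
adherence in the source protocol table (165/189 = 87.3% was printed as
95%, basis unstated — possibly completers-only); this package computes
attended/offered as defined, yielding 87%.

## Paired pre/post statistics

Small feasibility cohorts are analysed nonparametrically. Descriptives
are median and IQR with numpy's linear quantile interpolation.
Within-subject change uses the Wilcoxon signed-rank test with the
conventions of mainstream statistical packages: zero differences
dropped, mid-ranks for tied absolute differences, T = the smaller of
the positive and negative rank sums, tie-corrected normal
approximation *without* continuity correction,

    z = (T - n(n+1)/4) / sqrt( n(n+1)(2n+1)/24 - sum(t^3 - t)/48 ).

The exact method (n <= 20 after dropping zeros) computes the sign-flip
permutation distribution of the rank sum by dynamic programming over
doubled (hence integer) mid-ranks and reports P(min rank sum <=
observed T), which coincides with the usual doubled one-tail exact p
for tie-free data. The effect size is r = |z|/sqrt(n_eff), classified
small (r < 0.30), medium (0.30 <= r < 0.50), large (r >= 0.50). No
multiple-comparison correction is applied, consistent with the
exploratory character of feasibility analyses.

## Numerical and degenerate-input choices

- Percent rounding: half-up via floor(x + 0.5); verdicts compare the
  rounded integer to the threshold.
- Zero denominators raise an error naming the metric rather than
  returning NaN.
- All-zero paired differences raise a degenerate-sample error (the test
  statistic is undefined).
- Session logs are plain CSV; floats are written with Python's
  shortest round-trip representation, so write -> read -> write is
  byte-stable and seeded pipelines are byte-identical across runs.
- Duplicate game ids are rejected at catalog build, not deduplicated.
- Unknown configuration keys are rejected, with every offending key
  listed, so a misspelled zone boundary cannot silently revert to a
  default.

## Problem sizes used in the test-suite sweeps

The exhaustive progression checks cover all 22 anchors (and all 484
anchor pairs for reachability). The zero-noise convergence sweep uses
all 22 start anchors x 3 motor x 11 cognitive skill lattice points
(726 simulated trials of 16 sessions). Wilcoxon enumeration checks run
full 2^n enumeration for n <= 8 and cross-validate the asymptotic
branch against an independent implementation on larger seeded samples.
Simulated trials use the default cohort of 13 patients over 16
sessions.

## Known limitations

- The canonical grid layout (cognitive-minor row interleaving and the
  domain order) is a convention; a different interleaving would change
  which sub-categories are adjacent on the y-axis.
- The motor axis has only two positions, so motor progression
  saturates quickly; this reflects the 3-level adaptation itself.
- The patient model's linearity makes convergence proofs easy but
  understates the variability of real perceived-difficulty ratings.
- Feasibility verdicts depend on the rounding convention; a protocol
  that compares raw percentages would flip borderline cases (e.g. a
  raw 79.6% adherence rounds to 80 and passes here).
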