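# Methods

## The task and its model

The environment is a central zone surrounded by four areas (indexed 0–3 in
fixed north/east/south/west order). Each area holds five boxes that deplete
linearly in collection order: a **rich** area pays 8, 7, 6, 5, 4 coins and a
**poor** area 5, 4, 3, 2, 1. A trial is either a *rich environment* (all
four areas rich) or a *mixed environment* (exactly two rich, two poor, the
two rich placed uniformly among the C(4,2) = 6 arrangements). The global
label is always known (the task displays it at trial start); the placement
is hidden in mixed trials. Foraging time is capped by a battery of 50 s
(long) or 25 s (short) that runs only inside the areas.

All within-trial movement is abstracted into two per-subject durations:

* **T1** — collect the next box within the current area (default 3.41 s,
  the population average),
* **T2** — leave the current area, travel, and collect the first box of
  another area (default 6.10 s; T2 > T1 always).

There is no spatial geometry below this abstraction: timestamps advance in
T1/T2 jumps.

## The optimal agent

A fixed horizon rules out marginal-value-theorem rate maximization, so the
agent maximizes *total* coins by backward induction on a stochastic decision
tree. A state is `(time remaining, knowledge, location)`. Actions are
`stay_collect` (cost T1) and `move_collect(area)` (cost T2); an action is
feasible only if its full cost fits in the remaining time (no partial
collections at the buzzer) and its target still has boxes. The first entry
from the central zone is charged T1 by default — entering and collecting the
first box is a single collection-like act — configurable to T2 for
sensitivity checks.

Knowledge is per-area `(richness ∈ {rich, poor, unknown}, boxes taken)`.
An area's richness is revealed by its first collection. Because exactly two
areas are rich in a mixed trial, reveals are anti-correlated: the posterior
that an unexplored area is rich is the hypergeometric ratio
`(2 − #known-rich) / (4 − #known)`, and once two same-type areas are known a
*closure* step labels the remaining areas. Beliefs are computed by exact
enumeration of the consistent layouts, never sampled, so values are
bit-reproducible.

Moving into an unknown area is a chance node; its action value is the
reveal-probability-weighted expectation of the two branch values. State
values follow the coins-to-go convention (terminal value 0), which is
argmax-equivalent to accumulating coins along the path (unit-tested on small
trees). Ties are broken deterministically: stay before move, then lowest
area index — relevant only for symmetric unknown areas.

Numerics: with two action costs the reachable times form the lattice
`battery − i·T1 − j·T2`; memoization keys quantize time at 1 µs purely for
hashing while values are computed in full precision. The recursion runs on a
compact integer encoding of the knowledge state; one solver instance serves
all four conditions for a given timing. Solving all four conditions at the
population-average timing visits ~7.5×10⁴ states and takes well under a
second.

Validation uses an independent brute-force oracle (raw recursion over
observation histories with direct layout counting, no memoization and no
closure logic) on batteries admitting at most four actions, plus exact
enumeration checks: in a rich environment the optimal path is unique and
every statistic is an integer point mass; in a mixed environment the optimal
trajectory is deterministic *given* the layout, so Monte-Carlo means can be
compared to the 6-layout closed-form expectation.

## Rollouts

`run_trial` repeatedly queries a policy, applies costs and payouts, updates
knowledge with the true reveal plus closure, and stops when nothing is
feasible. `rollout_statistics` samples environments per condition and
reports means and full distributions of total coins, boxes opened, boxes in
the first area (the area of the first collection), unique areas visited
(areas with ≥ 1 collection), and average coins per box, with conditional
splits by first-area richness in mixed trials. The default trajectory count
is 10⁵; the acceptance script uses 10⁴ and the test suite 10²–2×10³ with
correspondingly widened Monte-Carlo tolerances. Logs serialize to JSON-lines
and to a flat event CSV; both round-trip losslessly.

## The synthetic cohort

The generator reproduces the study design: 34 subjects, two battery blocks
of 20 trials, block order counterbalanced 17/17, environment label drawn
i.i.d. per trial. The rich/mixed proportion is not printed in the study
description, so the default is a fair coin, exposed as `p_mixed`.

Human-likeness is deliberately minimal — the generator exists to exercise
the analysis pipeline with known ground truth, not to claim cognitive
fidelity:

* **Timing**: per-subject T1 ~ N(3.41, 0.53²), T2 ~ N(6.10, 0.72²),
  rejection-truncated to T2 > T1 > 0.5 s.
* **Decision noise**: softmax with temperature β on the optimal agent's
  action values (`P(a) ∝ exp(Q(a)/β)`). β = 0 reproduces the optimal policy
  exactly; large β approaches uniform choice. The default β = 2.0 is a
  moderate value on the coin scale: a one-coin value gap gives ≈ e^0.5 : 1
  odds, enough to produce systematic but imperfect behavior.
* **Movement jitter**: realized event intervals are the nominal cost plus
  N(0, 0.3²) s noise, floored at 0.5 s. Agents *plan* on their nominal
  clock; a jittered action that would overrun the battery is censored. This
  keeps the solver's time lattice intact and guarantees log timestamps never
  exceed the battery, at the price of a negligible truncation bias in
  timing-recovery (large late-trial jitters are occasionally dropped).
* **Learning modifiers** (off by default): per-trial multiplicative timing
  speed-up and temperature decay, used to generate across-trial improvement
  trends for testing the trend-fit machinery.

A fixed-leave-after-k heuristic policy is provided as an alternative plug-in
for sensitivity studies; it is not calibrated to anything.

What passing tests on this cohort do **not** show: anything about real
participants' coefficients, learning rates, or navigation. The generator has
no spatial search, no memory limits, no per-box location uncertainty — the
very factors the study identifies as sources of human suboptimality.

## Analysis stage

`summarize_trial` computes the six dependent variables; the identity
`avg_coins_per_box × boxes_collected = total_coins` holds exactly by
construction. The average box collection time is the mean interval between
consecutive collections within the same area and is missing when no such
pair exists (those trials are dropped from that variable's analyses only).
Same-area pairs spanning a re-entry are counted as within-area intervals.

`estimate_timing` pools within-area consecutive intervals (→ T1) and
cross-area consecutive intervals (→ T2) over all a subject's trials,
regardless of condition. On the noise-free generator recovery is exact; with
0.3 s jitter it is unbiased to within Monte-Carlo error.

`switch_records` replays the belief updates through each log to attach an
uncertainty-resolved flag to every collection, then classifies each
non-final event as *leave* (next collection elsewhere) or *stay*. Trial-final
events are censored: a time-out is not a decision, and a final free-choice
event followed by nothing cannot be classified. `switch_probability_table`
aggregates leave probabilities per environment label × current-area richness
× uncertainty-resolved cell (five feasible cells) × box ordinal.

`compare_to_optimal` runs two-sided Mann–Whitney tests per condition cell:
exact null for small tie-free samples, tie-corrected normal approximation
otherwise, and the documented convention p = 1 when both samples are a single
shared constant (the approximation's standard deviation vanishes there).
`learning_trend` fits OLS to per-trial-index cohort means; a constant series
returns slope 0 and R² = 0 by convention. Note that the deterministic
noise-free cohort can produce *statistically significant* yet practically
negligible slopes (residual variance is nearly zero), so stationarity checks
should bound the slope magnitude, not the p-value.

Mixed-effects (LMM/GLMM) coefficient estimation is intentionally out of
scope; the tidy per-trial and per-event tables are designed to drop into any
mixed-model package.

## Known limitations

* The solver assumes the forager knows the 2-rich/2-poor composition, the
  schedules, and its own T1/T2 exactly — it is an upper bound on
  performance, not a cognitive model.
* The cost of consulting the environment sensor is zero (the battery pauses
  in the central zone).
* The battery-grid monotonicity and dominance properties are verified on
  randomized timing samples, not proven.
* With learning modifiers on, each trial needs a fresh solver (timing
  changes break memo sharing), so long speeded cohorts are slower to
  generate.
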