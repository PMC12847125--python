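# patchforage

Optimal-agent modelling and behavioral analysis for a time-limited
patch-foraging task.

A forager with a fixed time budget (a 50 s or 25 s "battery") collects coins
from depleting boxes spread over four areas. Rich areas pay 8, 7, 6, 5, 4
coins per successive box; poor areas pay 5, 4, 3, 2, 1. Trials are either
*rich environments* (all areas rich) or *mixed environments* (two rich, two
poor, placement hidden until sampled). Collecting the next box in the
current area costs time T1; switching areas and collecting there costs
T2 > T1. The forager must therefore solve a stay-or-leave problem under a
hard deadline and partial observability — a regime where the marginal value
theorem does not apply, because the horizon is finite and the goal is total
reward, not reward rate.

The package is aimed at researchers who want to reproduce, probe, or extend
the model-based side of such patch-leaving experiments without access to
human data. It provides:

* **`task_model`** — the task's fixed structure: schedules, batteries,
  environment sampling, timing parameters, YAML-serializable config.
* **`belief`** — exact inference over the hidden rich/poor layout:
  hypergeometric reveal posteriors `(2 − #known-rich)/(4 − #known)`,
  forced-inference closure, layout enumeration.
* **`optimal_solver`** — the finite-horizon optimal agent: backward
  induction on the stochastic decision tree
  `V(s) = max_a [ E(coins(a)) + E(V(s'))]`, memoized on the
  `battery − i·T1 − j·T2` time lattice, with deterministic tie-breaks.
* **`rollout`** — trajectory simulation for any policy, Monte-Carlo and
  exact (layout-enumerated) statistics, JSON-lines/CSV trial logs.
* **`synthetic_cohort`** — a 34-subject synthetic study with
  counterbalanced battery blocks, drawn timing (T1 = 3.41 ± 0.53 s,
  T2 = 6.10 ± 0.72 s), softmax decision noise, and optional learning
  modifiers.
* **`analysis`** — the six per-trial dependent variables, per-subject
  T1/T2 estimation, uncertainty-aware area-switching probabilities,
  Mann–Whitney contrasts against the optimal reference, and OLS learning
  trends.

See `docs/methods.md` for the model, its assumptions, and numerical choices.

## Worked example

```python
from patchforage import (
    EnvLabel, LONG_BATTERY, SHORT_BATTERY, MEAN_TIMING, OptimalSolver,
    exact_optimal_statistics,
)

solver = OptimalSolver(MEAN_TIMING)   # T1 = 3.41 s, T2 = 6.10 s
print(solver.root_value(EnvLabel.RICH, LONG_BATTERY))    # 84.0
print(solver.root_value(EnvLabel.RICH, SHORT_BATTERY))   # 42.0
print(solver.root_value(EnvLabel.MIXED, LONG_BATTERY))   # 70.33333333333334

table = exact_optimal_statistics(solver, EnvLabel.MIXED, LONG_BATTERY)
print(table[["first_area_richness", "boxes_in_first_area", "total_coins"]])
```

```
  first_area_richness  boxes_in_first_area  total_coins
0                rich                    5           72
1                rich                    5           72
2                rich                    5           68
3                poor                    2           70
4                poor                    2           70
5                poor                    2           70
```

Reading the numbers: with average human timing, the optimal agent expects
84 coins in a long rich trial (a unique, deterministic path: three boxes in
each of the four areas) and 42 in a short one. In mixed trials the agent's
expected haul is 70.33 coins, and its strategy is extreme in exactly the way
finite-horizon reasoning predicts: if the first area sampled turns out rich
under a long battery it takes **all five** boxes before moving on, whereas a
poor first area under a short battery is abandoned after a **single** box
(the short-battery enumeration shows `boxes_in_first_area = 1` for poor
first areas).

A synthetic noisy cohort and its analysis, end to end:

```python
from patchforage import generate_study_logs, summaries_table, learning_trend
from patchforage.synthetic_cohort import CohortDesign, PopulationParams

logs, cohort = generate_study_logs(CohortDesign(), PopulationParams(), seed=42)
table = summaries_table(logs)        # 1360 trials x six dependent variables
print(table.groupby("battery_label")["total_coins"].mean())
```

```
battery_label
long     72.110294
short    37.302941
Name: total_coins, dtype: float64
```

The same machinery is exposed on the command line:

```bash
patchforage solve --env mixed_env --battery long --t1 3.41 --t2 6.10
patchforage simulate --env mixed_env --battery short --n 1000 --seed 0
patchforage cohort --seed 0 --logs-out logs.jsonl
patchforage analyze --logs logs.jsonl --out-dir results/
```

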