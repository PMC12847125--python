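"""Independent brute-force oracle for small foraging decision trees.

Computes expected coins-to-go by raw recursion over observation histories:
no memoization, no knowledge-state closure, no hypergeometric shortcut.
Reveal probabilities come from directly counting the environment layouts
consistent with the raw observations made so far, and inferable-but-unseen
areas stay formally unrevealed (their reveal chance simply degenerates to 0
or 1).  Deliberately shares no code with the solver under test; only
feasible at small depth (a handful of actions).
"""
from __future__ import annotations

import itertools

RICH_SEQ = (8, 7, 6, 5, 4)
POOR_SEQ = (5, 4, 3, 2, 1)
N_AREAS = 4
N_RICH_MIXED = 2


def _layouts(env_label: str) -> list[tuple[str, ...]]:
    """All environment layouts compatible with the global label."""
    if env_label == "rich_env":
        return [("rich",) * N_AREAS]
    layouts = []
    for rich_areas in itertools.combinations(range(N_AREAS), N_RICH_MIXED):
        layouts.append(tuple(
            "rich" if a in rich_areas else "poor" for a in range(N_AREAS)
        ))
    return layouts


def brute_force_value(
    env_label: str,
    time_remaining: float,
    t1: float,
    t2: float,
    first_move_cost: float | None = None,
    observed: dict[int, str] | None = None,
    boxes_taken: dict[int, int] | None = None,
    location: int | None = None,
) -> float:
    """Expected coins under optimal play, by exhaustive history recursion."""
    observed = dict(observed or {})
    boxes_taken = dict(boxes_taken or {})
    if first_move_cost is None:
        first_move_cost = t1
    consistent = [
        lay for lay in _layouts(env_label)
        if all(lay[a] == r for a, r in observed.items())
    ]
    assert consistent, "observations inconsistent with the environment label"

    def seq(richness: str) -> tuple[int, ...]:
        return RICH_SEQ if richness == "rich" else POOR_SEQ

    best = 0.0
    # stay and collect
    if location is not None and time_remaining >= t1:
        taken = boxes_taken.get(location, 0)
        if taken < len(RICH_SEQ):
            richness = observed[location]
            coins = seq(richness)[taken]
            value = coins + brute_force_value(
                env_label, time_remaining - t1, t1, t2, first_move_cost,
                observed, {**boxes_taken, location: taken + 1}, location,
            )
            best = max(best, value)
    # move and collect
    move_cost = first_move_cost if location is None else t2
    if time_remaining >= move_cost:
        for area in range(N_AREAS):
            if area == location:
                continue
            taken = boxes_taken.get(area, 0)
            if taken >= len(RICH_SEQ):
                continue
            if area in observed:
                richness = observed[area]
                coins = seq(richness)[taken]
                value = coins + brute_force_value(
                    env_label, time_remaining - move_cost, t1, t2,
                    first_move_cost, observed,
                    {**boxes_taken, area: taken + 1}, area,
                )
            else:
                value = 0.0
                n = len(consistent)
                for richness in ("rich", "poor"):
                    matching = sum(lay[area] == richness for lay in consistent)
                    if matching == 0:
                        continue
                    coins = seq(richness)[taken]
                    branch = coins + brute_force_value(
                        env_label, time_remaining - move_cost, t1, t2,
                        first_move_cost, {**observed, area: richness},
                        {**boxes_taken, area: taken + 1}, area,
                    )
                    value += (matching / n) * branch
            best = max(best, value)
    return best
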