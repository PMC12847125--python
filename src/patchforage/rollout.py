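"""Trajectory simulation and Monte-Carlo policy evaluation.

A *rollout* repeatedly queries a policy (optimal or noisy) in the task
environment, applies the time cost and coin payout of each chosen action,
updates the forager's knowledge with the true reveal, and stops when no
action fits in the remaining battery.  The resulting :class:`TrialLog` is the
common event format consumed by the analysis stage, whether the events come
from the optimal agent, a synthetic noisy agent, or externally supplied data
in the same format.

In a rich environment the optimal rollout is fully deterministic (no hidden
layout, deterministic tie-breaks), so every statistic is a point mass with
integer value.  In a mixed environment the only randomness of the optimal
agent is the hidden layout itself, so Monte-Carlo means over sampled layouts
can be checked exactly against the enumeration over the six arrangements.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .optimal_solver import (
    CENTRAL,
    AgentState,
    ForagingAction,
    OptimalSolver,
    action_cost,
    feasible_actions,
)
from .task_model import (
    AreaRichness,
    BatteryCondition,
    CoinSchedule,
    DEFAULT_SCHEDULE,
    EnvLabel,
    EnvironmentConfig,
    SubjectTiming,
    sample_environment,
)

Policy = Callable[[AgentState, np.random.Generator], ForagingAction]


@dataclass(frozen=True)
class TrialEvent:
    """One box collection: when, by which action, where, which box, how much."""

    timestamp: float  # seconds from trial start, at the moment of collection
    action_kind: str  # "stay_collect" or "move_collect"
    area: int
    box_ordinal: int  # 1..5 within the area
    coins: int


@dataclass
class TrialLog:
    """Ordered event record of one trial, plus its hidden truth and labels."""

    subject_id: str
    trial_index: int
    env_label: EnvLabel
    battery_label: str
    battery_duration: float
    config: EnvironmentConfig
    events: list[TrialEvent] = field(default_factory=list)

    def validate(self, schedule: CoinSchedule = DEFAULT_SCHEDULE) -> None:
        """Raise ``ValueError`` naming the first violated log invariant."""
        last_t = 0.0
        ordinals: dict[int, int] = {}
        for ev in self.events:
            if ev.timestamp <= last_t:
                raise ValueError(f"timestamps not strictly increasing at {ev}")
            last_t = ev.timestamp
            expected_ord = ordinals.get(ev.area, 0) + 1
            if ev.box_ordinal != expected_ord:
                raise ValueError(
                    f"box ordinal {ev.box_ordinal} in area {ev.area}, "
                    f"expected {expected_ord}"
                )
            ordinals[ev.area] = ev.box_ordinal
            truth = self.config.area_richness[ev.area]
            expected_coins = schedule.sequence_for(truth)[ev.box_ordinal - 1]
            if ev.coins != expected_coins:
                raise ValueError(
                    f"coins {ev.coins} do not match the {truth.value} schedule "
                    f"for box {ev.box_ordinal}"
                )
        if last_t > self.battery_duration + 1e-9:
            raise ValueError("events exceed the battery duration")

    @property
    def total_coins(self) -> int:
        return sum(ev.coins for ev in self.events)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "trial_index": self.trial_index,
            "env_label": self.env_label.value,
            "battery_label": self.battery_label,
            "battery_duration": self.battery_duration,
            "area_richness": [r.value for r in self.config.area_richness],
            "events": [
                [ev.timestamp, ev.action_kind, ev.area, ev.box_ordinal, ev.coins]
                for ev in self.events
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TrialLog":
        label = EnvLabel(payload["env_label"])
        config = EnvironmentConfig(
            tuple(AreaRichness(r) for r in payload["area_richness"]), label
        )
        return cls(
            subject_id=payload["subject_id"],
            trial_index=int(payload["trial_index"]),
            env_label=label,
            battery_label=payload["battery_label"],
            battery_duration=float(payload["battery_duration"]),
            config=config,
            events=[
                TrialEvent(float(t), kind, int(a), int(o), int(c))
                for t, kind, a, o, c in payload["events"]
            ],
        )


@dataclass(frozen=True)
class RolloutConfig:
    n_trajectories: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


def run_trial(
    policy: Policy,
    env: EnvironmentConfig,
    battery: BatteryCondition | float,
    timing: SubjectTiming,
    rng: np.random.Generator,
    *,
    schedule: CoinSchedule = DEFAULT_SCHEDULE,
    first_move_cost: str = "t1",
    interval_jitter_sd: float = 0.0,
    subject_id: str = "agent",
    trial_index: int = 0,
) -> TrialLog:
    """Simulate one trial of ``policy`` in environment ``env``.

    ``battery`` is one of the two task conditions, or a bare duration in
    seconds (labelled ``custom``) for reduced-horizon experiments.  The
    forager plans on its nominal clock (actions cost exactly ``T1`` or
    ``T2``); when ``interval_jitter_sd > 0`` the *realized* event times are
    additionally jittered to emulate variable human movement durations.  A
    jittered action that would overrun the battery is not executed, so logged
    timestamps never exceed the battery duration.
    """
    from .belief import KnowledgeState  # local to avoid polluting module surface

    if isinstance(battery, BatteryCondition):
        duration, battery_label = battery.duration, battery.label.value
    else:
        duration, battery_label = float(battery), "custom"
    state = AgentState(duration, KnowledgeState.initial(env.label), CENTRAL)
    log = TrialLog(
        subject_id=subject_id,
        trial_index=trial_index,
        env_label=env.label,
        battery_label=battery_label,
        battery_duration=duration,
        config=env,
    )
    clock = 0.0  # realized elapsed time
    while True:
        allowed = feasible_actions(state, timing, first_move_cost)
        if not allowed:
            break
        action = policy(state, rng)
        if action not in allowed:
            raise ValueError(
                f"policy chose infeasible action {action} in state "
                f"{state.knowledge.to_tuple_string()} at t={state.time_remaining:.2f}"
            )
        cost = action_cost(state, action, timing, first_move_cost)
        realized = cost
        if interval_jitter_sd > 0:
            realized = max(0.5, cost + rng.normal(0.0, interval_jitter_sd))
            if clock + realized > duration:
                break  # action would overrun the battery; trial ends
        area = state.location if action.kind == "stay_collect" else action.target
        truth = env.area_richness[area]
        taken = state.knowledge.boxes_taken(area)
        coins = schedule.sequence_for(truth)[taken]
        clock += realized
        log.events.append(
            TrialEvent(clock, action.kind, area, taken + 1, int(coins))
        )
        knowledge = state.knowledge.reveal(area, truth).collect(area)
        state = AgentState(state.time_remaining - cost, knowledge, area)
    return log


def _trial_stats(log: TrialLog) -> dict:
    events = log.events
    boxes = len(events)
    total = sum(ev.coins for ev in events)
    first_area = events[0].area if events else None
    boxes_first = sum(ev.area == first_area for ev in events) if events else 0
    areas = len({ev.area for ev in events})
    first_richness = (
        log.config.area_richness[first_area].value if events else None
    )
    return {
        "total_coins": total,
        "boxes_collected": boxes,
        "boxes_in_first_area": boxes_first,
        "n_unique_areas": areas,
        "avg_coins_per_box": total / boxes if boxes else np.nan,
        "first_area_richness": first_richness,
    }


@dataclass
class RolloutSummary:
    """Per-trajectory statistics plus their means for one condition."""

    trials: pd.DataFrame
    env_label: EnvLabel
    battery: BatteryCondition

    STAT_COLUMNS = (
        "total_coins",
        "boxes_collected",
        "boxes_in_first_area",
        "n_unique_areas",
        "avg_coins_per_box",
    )

    @property
    def means(self) -> pd.Series:
        return self.trials[list(self.STAT_COLUMNS)].mean()

    def by_first_area_richness(self) -> pd.DataFrame:
        """Conditional means split by the true richness of the first area."""
        return (
            self.trials.groupby("first_area_richness")[list(self.STAT_COLUMNS)]
            .mean()
        )


def rollout_statistics(
    policy: Policy,
    env_label: EnvLabel | str,
    battery: BatteryCondition,
    timing: SubjectTiming,
    cfg: RolloutConfig,
    *,
    schedule: CoinSchedule = DEFAULT_SCHEDULE,
    first_move_cost: str = "t1",
) -> RolloutSummary:
    """Monte-Carlo evaluation of a policy over sampled environments."""
    env_label = EnvLabel(env_label) if not isinstance(env_label, EnvLabel) else env_label
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i in range(cfg.n_trajectories):
        env = sample_environment(env_label, rng)
        log = run_trial(
            policy, env, battery, timing, rng,
            schedule=schedule, first_move_cost=first_move_cost, trial_index=i,
        )
        rows.append(_trial_stats(log))
    return RolloutSummary(pd.DataFrame(rows), env_label, battery)


def exact_optimal_statistics(
    solver: OptimalSolver,
    env_label: EnvLabel | str,
    battery: BatteryCondition,
) -> pd.DataFrame:
    """Exact per-layout statistics of the optimal agent for one condition.

    Given the true layout, the optimal trajectory is deterministic (reveals
    are fixed by the layout and tie-breaks are deterministic), so the exact
    expectation of any statistic is the probability-weighted mean over the
    consistent layouts: one layout for a rich environment, six equiprobable
    ones for a mixed environment.  Returns one row per layout with its
    probability — the independent check for Monte-Carlo rollouts.
    """
    from .belief import KnowledgeState, consistent_configs

    env_label = EnvLabel(env_label) if not isinstance(env_label, EnvLabel) else env_label
    k0 = KnowledgeState.initial(env_label)
    rng = np.random.default_rng(0)  # optimal policy ignores the stream
    rows = []
    for config, prob in consistent_configs(k0):
        log = run_trial(
            solver.as_policy(), config, battery, solver.timing, rng,
            schedule=solver.schedule, first_move_cost=solver.first_move_cost,
        )
        row = _trial_stats(log)
        row["probability"] = prob
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TrialLog serialization: JSON-lines (one trial per line) and a flat event CSV

def write_logs_jsonl(logs: Iterable[TrialLog], path: str | Path) -> None:
    with open(path, "w") as fh:
        for log in logs:
            fh.write(json.dumps(log.to_dict()) + "\n")


def read_logs_jsonl(path: str | Path) -> list[TrialLog]:
    logs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                logs.append(TrialLog.from_dict(json.loads(line)))
    return logs


_CSV_FIELDS = [
    "subject_id", "trial_index", "env_label", "battery_label",
    "battery_duration", "area_richness", "timestamp", "action_kind",
    "area", "box_ordinal", "coins",
]


def write_logs_csv(logs: Iterable[TrialLog], path: str | Path) -> None:
    """Flat event table: one row per collection, trial metadata repeated."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for log in logs:
            richness = "".join(
                "R" if r is AreaRichness.RICH else "P"
                for r in log.config.area_richness
            )
            for ev in log.events:
                writer.writerow({
                    "subject_id": log.subject_id,
                    "trial_index": log.trial_index,
                    "env_label": log.env_label.value,
                    "battery_label": log.battery_label,
                    "battery_duration": repr(log.battery_duration),
                    "area_richness": richness,
                    "timestamp": repr(ev.timestamp),
                    "action_kind": ev.action_kind,
                    "area": ev.area,
                    "box_ordinal": ev.box_ordinal,
                    "coins": ev.coins,
                })


def read_logs_csv(path: str | Path) -> list[TrialLog]:
    logs: dict[tuple, TrialLog] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["subject_id"], int(row["trial_index"]))
            if key not in logs:
                label = EnvLabel(row["env_label"])
                richness = tuple(
                    AreaRichness.RICH if ch == "R" else AreaRichness.POOR
                    for ch in row["area_richness"]
                )
                logs[key] = TrialLog(
                    subject_id=row["subject_id"],
                    trial_index=int(row["trial_index"]),
                    env_label=label,
                    battery_label=row["battery_label"],
                    battery_duration=float(row["battery_duration"]),
                    config=EnvironmentConfig(richness, label),
                )
            logs[key].events.append(
                TrialEvent(
                    float(row["timestamp"]), row["action_kind"],
                    int(row["area"]), int(row["box_ordinal"]), int(row["coins"]),
                )
            )
    return list(logs.values())
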