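"""Behavioral analysis of trial logs.

Computes, from :class:`~patchforage.rollout.TrialLog` collections, the six
per-trial dependent variables of the study (total coins, boxes collected in
the first area, boxes collected, average coins per box, number of unique
areas visited, and average within-area box collection time), per-subject
timing estimates, descriptive area-switching probabilities stratified by
uncertainty resolution, Mann–Whitney contrasts between an agent sample and
the optimal reference, and ordinary-least-squares learning trends across
trials.  Mixed-model coefficient estimation is deliberately not included:
the module emits tidy per-trial tables that any mixed-model package can
consume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .belief import KnowledgeState, uncertainty_resolved
from .rollout import TrialLog


@dataclass(frozen=True)
class TrialSummary:
    """The six dependent variables of one trial, plus identifying labels."""

    subject_id: str
    trial_index: int
    env_label: str
    battery_label: str
    total_coins: int
    boxes_in_first_area: int
    boxes_collected: int
    avg_coins_per_box: float
    n_unique_areas: int
    avg_box_collection_time: float  # NaN when no within-area interval exists
    first_area_richness: str | None


@dataclass(frozen=True)
class TimingEstimate:
    """Per-subject ``T1``/``T2`` estimates with contributing interval counts."""

    t1_hat: float
    t2_hat: float
    n_t1: int
    n_t2: int


def summarize_trial(log: TrialLog) -> TrialSummary:
    """Compute the six dependent variables from one trial log.

    The *first area* is the area of the first collection event; the average
    box collection time is the mean interval between consecutive collections
    within the same area (NaN when the trial has no such pair).
    """
    log.validate()
    events = log.events
    boxes = len(events)
    total = sum(ev.coins for ev in events)
    if events:
        first_area = events[0].area
        boxes_first = sum(ev.area == first_area for ev in events)
        first_richness = log.config.area_richness[first_area].value
    else:
        first_area, boxes_first, first_richness = None, 0, None
    intervals = [
        b.timestamp - a.timestamp
        for a, b in zip(events, events[1:])
        if a.area == b.area
    ]
    return TrialSummary(
        subject_id=log.subject_id,
        trial_index=log.trial_index,
        env_label=log.env_label.value,
        battery_label=log.battery_label,
        total_coins=total,
        boxes_in_first_area=boxes_first,
        boxes_collected=boxes,
        avg_coins_per_box=total / boxes if boxes else math.nan,
        n_unique_areas=len({ev.area for ev in events}),
        avg_box_collection_time=(
            sum(intervals) / len(intervals) if intervals else math.nan
        ),
        first_area_richness=first_richness,
    )


def summaries_table(logs: list[TrialLog]) -> pd.DataFrame:
    """Tidy per-trial table, one row per trial, ready for any model fit."""
    return pd.DataFrame([summarize_trial(log).__dict__ for log in logs])


def estimate_timing(logs: list[TrialLog]) -> TimingEstimate:
    """Estimate a subject's ``T1`` and ``T2`` from their trial logs.

    ``T1`` is the mean interval between consecutive collections in the same
    area and ``T2`` the mean interval between consecutive collections in
    different areas (leave + travel + first collection), pooled over every
    trial regardless of condition.  The interval from trial start to the
    first collection is excluded (it is the central-zone entry, whose cost
    convention is configurable).
    """
    same, cross = [], []
    for log in logs:
        for a, b in zip(log.events, log.events[1:]):
            (same if a.area == b.area else cross).append(b.timestamp - a.timestamp)
    if not same or not cross:
        raise ValueError(
            "need at least one within-area and one cross-area interval"
        )
    return TimingEstimate(
        t1_hat=float(np.mean(same)),
        t2_hat=float(np.mean(cross)),
        n_t1=len(same),
        n_t2=len(cross),
    )


def switch_records(logs: list[TrialLog]) -> pd.DataFrame:
    """Per-collection stay/leave records with belief context.

    For every collection event except the last of each trial, records
    whether the next collection happened in a different area (a *leave*),
    the box ordinal, the true richness of the current area, and whether the
    environment layout was already inferable at that moment (computed by
    replaying the belief updates through the log).  Trial-final events are
    censored: a time-out is not a decision, and a final event followed by
    nothing cannot be classified as stay or leave.
    """
    rows = []
    for log in logs:
        k = KnowledgeState.initial(log.env_label)
        visit_order: dict[int, int] = {}
        for i, ev in enumerate(log.events):
            truth = log.config.area_richness[ev.area]
            k = k.reveal(ev.area, truth).collect(ev.area)
            if ev.area not in visit_order:
                visit_order[ev.area] = len(visit_order) + 1
            if i + 1 >= len(log.events):
                continue  # censored trial-final event
            rows.append({
                "subject_id": log.subject_id,
                "trial_index": log.trial_index,
                "env_label": log.env_label.value,
                "battery_label": log.battery_label,
                "area": ev.area,
                "box_ordinal": ev.box_ordinal,
                "area_richness": truth.value,
                "uncertainty_resolved": uncertainty_resolved(k),
                "area_visit_order": visit_order[ev.area],
                "left_after": log.events[i + 1].area != ev.area,
            })
    return pd.DataFrame(rows)


def switch_probability_table(logs: list[TrialLog]) -> pd.DataFrame:
    """Leave probability after each box, per feasible condition cell.

    Cells are combinations of environment label × current-area richness ×
    uncertainty-resolved; only five are feasible (a rich environment has no
    poor areas and no unresolved uncertainty).  Counts accompany each
    probability so downstream tests can weight cells.
    """
    records = switch_records(logs)
    if records.empty:
        return pd.DataFrame(
            columns=["env_label", "area_richness", "uncertainty_resolved",
                     "box_ordinal", "n", "n_left", "p_leave"]
        )
    grouped = (
        records.groupby(
            ["env_label", "area_richness", "uncertainty_resolved", "box_ordinal"]
        )["left_after"]
        .agg(n="size", n_left="sum")
        .reset_index()
    )
    grouped["p_leave"] = grouped["n_left"] / grouped["n"]
    return grouped


def mannwhitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with a documented exact-tie convention.

    Uses the exact null distribution for small samples without ties and the
    tie-corrected normal approximation otherwise.  When every observation in
    both samples is identical the statistic carries no evidence either way
    and ``p = 1`` is returned (the normal approximation would divide by a
    zero standard deviation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size <= 20 and y.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_to_optimal(
    agent: pd.DataFrame,
    optimal: pd.DataFrame,
    variable: str,
    grouping: list[str],
) -> pd.DataFrame:
    """Mann–Whitney contrast of agent vs optimal samples per condition cell.

    ``agent`` and ``optimal`` are tidy per-trial tables (see
    :func:`summaries_table`); ``grouping`` lists the columns defining the
    cells (e.g. ``["battery_label", "env_label"]`` or additionally
    ``first_area_richness``).  Reports U, the two-sided p-value, and the
    direction of the median difference.  Raises on an empty cell.
    """
    rows = []
    agent_groups = agent.groupby(grouping)
    optimal_groups = dict(iter(optimal.groupby(grouping)))
    for key, a_cell in agent_groups:
        if key not in optimal_groups:
            raise ValueError(f"optimal reference has no cell {key}")
        o_cell = optimal_groups[key]
        a_vals = a_cell[variable].dropna().to_numpy()
        o_vals = o_cell[variable].dropna().to_numpy()
        if a_vals.size == 0 or o_vals.size == 0:
            raise ValueError(f"empty cell {key} for variable {variable}")
        u, p = mannwhitney(a_vals, o_vals)
        diff = float(np.median(a_vals) - np.median(o_vals))
        row = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        row.update({
            "variable": variable,
            "u_statistic": u,
            "p_value": p,
            "median_agent": float(np.median(a_vals)),
            "median_optimal": float(np.median(o_vals)),
            "direction": "agent_higher" if diff > 0 else
                         ("agent_lower" if diff < 0 else "equal"),
            "n_agent": int(a_vals.size),
            "n_optimal": int(o_vals.size),
        })
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def learning_trend(summaries: pd.DataFrame, variable: str) -> TrendFit:
    """OLS fit of the per-trial-index cohort mean against trial number.

    Averages ``variable`` over subjects for each trial index (1..n) and
    regresses the means on the index; mirrors a scatter-plus-regression-line
    view of across-trial learning.  A constant variable yields slope 0 and
    R² = 0.
    """
    means = (
        summaries.dropna(subset=[variable])
        .groupby("trial_index")[variable]
        .mean()
        .sort_index()
    )
    if len(means) < 3:
        raise ValueError("need at least three trial indices for a trend")
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return TrendFit(0.0, float(y[0]), 0.0, 1.0, len(means))
    fit = stats.linregress(x, y)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_points=len(means),
    )
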