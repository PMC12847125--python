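"""Synthetic participant cohort with the study's design structure.

The generator reproduces the experimental design — 34 subjects, two
battery blocks of 20 trials each with counterbalanced block order, and a
random rich/mixed environment assignment per trial — while replacing human
decision making with a tunable departure from optimality.  Human-likeness is
modelled by exactly three ingredients:

* per-subject timing drawn from the reported population distribution
  (``T1 = 3.41 ± 0.53 s``, ``T2 = 6.10 ± 0.72 s``, truncated to keep
  ``T2 > T1 > 0``),
* softmax decision noise with temperature ``beta`` on the optimal agent's
  action values (``beta = 0`` recovers the optimal policy exactly), and
* realized-movement jitter around the nominal ``T1``/``T2`` durations.

Optional learning modifiers (a per-trial multiplicative timing speed-up and
temperature decay) let the generator produce across-trial improvement
trends; both default to off.  The generator makes no claim of cognitive
fidelity — its job is to exercise the analysis pipeline end to end with
data whose ground truth is known.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optimal_solver import AgentState, ForagingAction, OptimalSolver
from .rollout import TrialLog, run_trial
from .task_model import (
    BatteryCondition,
    BatteryLabel,
    EnvLabel,
    SubjectTiming,
    TaskConfig,
    DEFAULT_TASK,
    sample_environment,
)

#: hard floor on any drawn or sped-up duration, in seconds
TIMING_FLOOR = 0.5

#: reported population moments of the timing parameters
T1_MEAN, T1_SD = 3.41, 0.53
T2_MEAN, T2_SD = 6.10, 0.72


@dataclass(frozen=True)
class CohortDesign:
    """Study design: block structure, group balance, trial randomization."""

    n_subjects: int = 34
    trials_per_block: int = 20
    p_mixed: float = 0.5  # per-trial probability of a mixed environment

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one subject and one trial per block")
        if not 0.0 <= self.p_mixed <= 1.0:
            raise ValueError("p_mixed must be a probability")

    @property
    def n_trials(self) -> int:
        return 2 * self.trials_per_block


@dataclass(frozen=True)
class SyntheticAgentParams:
    """One synthetic subject: timing, decision noise, learning modifiers."""

    timing: SubjectTiming
    beta: float = 0.0  # softmax temperature on action values; 0 = optimal
    interval_jitter_sd: float = 0.0  # realized-duration noise, seconds
    timing_speedup_per_trial: float = 1.0  # multiplicative, <1 = gets faster
    beta_decay_per_trial: float = 1.0  # multiplicative, <1 = less noisy

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.interval_jitter_sd < 0:
            raise ValueError("jitter sd must be non-negative")
        if not 0 < self.timing_speedup_per_trial <= 1.0:
            raise ValueError("speed-up factor must be in (0, 1]")
        if not 0 < self.beta_decay_per_trial <= 1.0:
            raise ValueError("beta decay factor must be in (0, 1]")

    def timing_on_trial(self, trial_index: int) -> SubjectTiming:
        """Timing on 1-based trial ``trial_index`` after the speed-up."""
        factor = self.timing_speedup_per_trial ** (trial_index - 1)
        return SubjectTiming(
            t1=max(TIMING_FLOOR, self.timing.t1 * factor),
            t2=max(TIMING_FLOOR + 1e-6, self.timing.t2 * factor),
        )

    def beta_on_trial(self, trial_index: int) -> float:
        return self.beta * self.beta_decay_per_trial ** (trial_index - 1)


@dataclass(frozen=True)
class PopulationParams:
    """Distribution the per-subject parameters are drawn from."""

    t1_mean: float = T1_MEAN
    t1_sd: float = T1_SD
    t2_mean: float = T2_MEAN
    t2_sd: float = T2_SD
    beta: float = 2.0
    interval_jitter_sd: float = 0.3
    timing_speedup_per_trial: float = 1.0
    beta_decay_per_trial: float = 1.0


#: moderate decision noise and realistic movement jitter; the package default
DEFAULT_POPULATION = PopulationParams()

#: noise-free population: every subject is the optimal agent with drawn timing
NOISELESS_POPULATION = PopulationParams(beta=0.0, interval_jitter_sd=0.0)


@dataclass(frozen=True)
class ScheduledTrial:
    """One row of the cohort's trial schedule."""

    subject_id: str
    trial_index: int  # 1..40, experiment order
    block: int  # 1 or 2
    battery_label: BatteryLabel
    env_label: EnvLabel


@dataclass
class Cohort:
    design: CohortDesign
    subjects: dict[str, SyntheticAgentParams]
    groups: dict[str, str]  # subject id -> "long_first" | "short_first"
    schedule: list[ScheduledTrial] = field(default_factory=list)


def _draw_timing(rng: np.random.Generator, pop: PopulationParams) -> SubjectTiming:
    """Truncated-normal timing draw with ``T2 > T1 > TIMING_FLOOR``."""
    for _ in range(1000):
        t1 = rng.normal(pop.t1_mean, pop.t1_sd)
        t2 = rng.normal(pop.t2_mean, pop.t2_sd)
        if t1 > TIMING_FLOOR and t2 > t1:
            return SubjectTiming(t1=t1, t2=t2)
    raise RuntimeError("timing population rejects everything; check moments")


def sample_cohort(
    design: CohortDesign,
    population: PopulationParams,
    seed: int,
) -> Cohort:
    """Draw subjects, balanced block-order groups, and the full trial schedule.

    Half the subjects (rounded up) see the long-battery block first and half
    the short one, mirroring the counterbalanced design; environment labels
    are i.i.d. per trial.
    """
    rng = np.random.default_rng(seed)
    subjects: dict[str, SyntheticAgentParams] = {}
    groups: dict[str, str] = {}
    n = design.n_subjects
    order = rng.permutation(n)
    long_first = {int(i) for i in order[: (n + 1) // 2]}
    schedule: list[ScheduledTrial] = []
    for s in range(n):
        sid = f"S{s:02d}"
        subjects[sid] = SyntheticAgentParams(
            timing=_draw_timing(rng, population),
            beta=population.beta,
            interval_jitter_sd=population.interval_jitter_sd,
            timing_speedup_per_trial=population.timing_speedup_per_trial,
            beta_decay_per_trial=population.beta_decay_per_trial,
        )
        groups[sid] = "long_first" if s in long_first else "short_first"
        for trial in range(1, design.n_trials + 1):
            block = 1 if trial <= design.trials_per_block else 2
            if groups[sid] == "long_first":
                battery = BatteryLabel.LONG if block == 1 else BatteryLabel.SHORT
            else:
                battery = BatteryLabel.SHORT if block == 1 else BatteryLabel.LONG
            env = (
                EnvLabel.MIXED
                if rng.random() < design.p_mixed
                else EnvLabel.RICH
            )
            schedule.append(ScheduledTrial(sid, trial, block, battery, env))
    return Cohort(design, subjects, groups, schedule)


def noisy_policy(
    params: SyntheticAgentParams, solver: OptimalSolver, beta: float | None = None
):
    """Softmax policy over the optimal agent's action values.

    With temperature ``beta`` the probability of a feasible action ``a`` is
    proportional to ``exp(Q(a) / beta)``; ``beta = 0`` degenerates to the
    optimal policy (including its tie-breaks), and large ``beta`` approaches
    a uniform choice among feasible actions.
    """
    if beta is None:
        beta = params.beta

    def policy(state: AgentState, rng: np.random.Generator) -> ForagingAction:
        if beta == 0.0:
            return solver.optimal_policy(state)
        ranked = solver.action_values(state)
        if not ranked:
            raise ValueError("no feasible action: terminal state")
        q = np.array([av.value for av in ranked])
        logits = (q - q.max()) / beta
        weights = np.exp(logits)
        probs = weights / weights.sum()
        choice = rng.choice(len(ranked), p=probs)
        return ranked[choice].action

    return policy


def generate_study_logs(
    design: CohortDesign = CohortDesign(),
    population: PopulationParams = DEFAULT_POPULATION,
    seed: int = 0,
    task: TaskConfig = DEFAULT_TASK,
) -> tuple[list[TrialLog], Cohort]:
    """Simulate the full synthetic study; one :class:`TrialLog` per trial.

    The per-subject random stream is derived from the master seed, so the
    whole dataset is reproducible from ``(design, population, seed)``.
    """
    cohort = sample_cohort(design, population, seed)
    master = np.random.default_rng(seed + 1)
    streams = {sid: np.random.default_rng(s) for sid, s in
               zip(cohort.subjects, master.integers(0, 2**31 - 1, len(cohort.subjects)))}
    logs: list[TrialLog] = []
    solvers: dict[tuple[str, SubjectTiming], OptimalSolver] = {}
    for item in cohort.schedule:
        params = cohort.subjects[item.subject_id]
        rng = streams[item.subject_id]
        timing = params.timing_on_trial(item.trial_index)
        key = (item.subject_id, timing)
        if key not in solvers:
            if len(solvers) > 64:  # cap memory when learning modifiers are on
                solvers.clear()
            solvers[key] = OptimalSolver.from_task_config(timing, task)
        solver = solvers[key]
        policy = noisy_policy(params, solver, beta=params.beta_on_trial(item.trial_index))
        env = sample_environment(item.env_label, rng)
        battery = BatteryCondition.from_label(item.battery_label)
        log = run_trial(
            policy, env, battery, timing, rng,
            schedule=task.schedule,
            first_move_cost=task.first_move_cost,
            interval_jitter_sd=params.interval_jitter_sd,
            subject_id=item.subject_id,
            trial_index=item.trial_index,
        )
        logs.append(log)
    return logs, cohort


def leave_after_k_policy(k: int, solver: OptimalSolver):
    """Fixed-heuristic plug-in: always leave an area after ``k`` collections.

    Provided as an alternative to softmax noise for sensitivity studies of
    the analysis stage; moves fall back to the optimal agent's choice among
    feasible moves (or stay, if no move fits the remaining time).
    """
    if k < 1:
        raise ValueError("k must be at least 1")

    def policy(state: AgentState, rng: np.random.Generator) -> ForagingAction:
        allowed = solver.feasible_actions(state)
        if not allowed:
            raise ValueError("no feasible action: terminal state")
        in_area = state.location is not None
        taken = state.knowledge.boxes_taken(state.location) if in_area else 0
        moves = [a for a in allowed if a.kind == "move_collect"]
        if in_area and taken >= k and moves:
            ranked = [av for av in solver.action_values(state) if av.action in moves]
            return max(ranked, key=lambda av: av.value).action
        stays = [a for a in allowed if a.kind == "stay_collect"]
        if stays:
            return stays[0]
        return solver.optimal_policy(state)

    return policy
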