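"""Finite-horizon optimal foraging agent.

The stay-or-leave problem with a fixed time budget cannot be solved by
rate-maximization arguments (marginal value theorem), which assume an
infinite horizon; instead the agent maximizes *total* coins by backward
induction on a stochastic decision tree.  A tree node is an
:class:`AgentState`: remaining battery time, the current knowledge of the
environment, and the current area.  From a node the agent may stay and
collect the next box (cost ``T1``) or move to another non-empty area and
collect its first box there (cost ``T2``); an action is feasible only if its
full cost fits in the remaining time.  Moving into an unexplored area of a
mixed environment is a chance node: the area is revealed rich or poor with
the exact posterior probability supplied by the belief module, and the
action value is the corresponding expectation.  State values follow the
coins-to-go convention (terminal nodes are worth zero), which yields the
same argmax decisions as accumulating coins along the path.

With only two action costs the reachable times form a small lattice
``battery − i·T1 − j·T2``, so memoizing on (quantized time, knowledge,
location) makes exact solution cheap.  The recursion runs on a compact
integer encoding of the knowledge state; the dataclass types are the public
interface.
"""
from __future__ import annotations

from dataclasses import dataclass

from .belief import KnowledgeState, apply_closure
from .task_model import (
    BOXES_PER_AREA,
    MIXED_N_RICH,
    N_AREAS,
    AreaRichness,
    BatteryCondition,
    CoinSchedule,
    DEFAULT_SCHEDULE,
    EnvLabel,
    SubjectTiming,
    TaskConfig,
)

#: location value for the pre-first-action central zone
CENTRAL = None
_CENTRAL_CODE = -1

#: time quantum used only to build hashable memo keys; values stay full precision
TIME_QUANTUM = 1e-6

# per-area knowledge codes: 0 = unknown (no boxes taken);
# 1 + b = rich with b boxes taken; 7 + b = poor with b boxes taken (b in 0..5)
_UNKNOWN = 0
_RICH0 = 1
_POOR0 = 1 + BOXES_PER_AREA + 1  # 7


def _code(richness: AreaRichness, boxes: int) -> int:
    if richness is AreaRichness.UNKNOWN:
        return _UNKNOWN
    base = _RICH0 if richness is AreaRichness.RICH else _POOR0
    return base + boxes


def _boxes_of(code: int) -> int:
    if code == _UNKNOWN:
        return 0
    return code - _RICH0 if code < _POOR0 else code - _POOR0


def _is_rich(code: int) -> bool:
    return _RICH0 <= code < _POOR0


@dataclass(frozen=True)
class ForagingAction:
    """``stay_collect`` (target None) or ``move_collect`` into ``target``."""

    kind: str
    target: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stay_collect", "move_collect"):
            raise ValueError(f"unknown action kind: {self.kind}")
        if self.kind == "move_collect" and self.target is None:
            raise ValueError("move_collect needs a target area")
        if self.kind == "stay_collect" and self.target is not None:
            raise ValueError("stay_collect takes no target")


STAY = ForagingAction("stay_collect")


def move(target: int) -> ForagingAction:
    return ForagingAction("move_collect", target)


@dataclass(frozen=True)
class AgentState:
    """Decision-tree node: remaining time, knowledge, current area.

    ``location`` is ``None`` only at the root, before the forager has left
    the central zone (where the battery does not run).
    """

    time_remaining: float
    knowledge: KnowledgeState
    location: int | None

    def __post_init__(self) -> None:
        if self.time_remaining < 0:
            raise ValueError("negative remaining time")
        if self.location is not None and not 0 <= self.location < N_AREAS:
            raise ValueError(f"bad location: {self.location}")


@dataclass(frozen=True)
class ActionValue:
    action: ForagingAction
    value: float


def action_cost(
    state: AgentState, action: ForagingAction, timing: SubjectTiming,
    first_move_cost: str = "t1",
) -> float:
    """Seconds consumed by an action from a given state.

    Staying costs ``T1`` and switching areas ``T2``, except that the very
    first entry from the central zone — walking into an area and collecting
    its first box — is charged ``T1`` by default (configurable to ``T2``).
    """
    if action.kind == "stay_collect":
        return timing.t1
    if state.location is CENTRAL:
        return timing.t1 if first_move_cost == "t1" else timing.t2
    return timing.t2


def feasible_actions(
    state: AgentState, timing: SubjectTiming, first_move_cost: str = "t1"
) -> list[ForagingAction]:
    """Actions whose full time cost fits and whose target still has boxes.

    Staying requires boxes left in the current area; moving excludes the
    current area.  The empty list marks a terminal node (no partial
    collections at the buzzer).  Order is the tie-break order: stay first,
    then moves by ascending area index.
    """
    actions: list[ForagingAction] = []
    k = state.knowledge
    if (
        state.location is not CENTRAL
        and k.boxes_taken(state.location) < BOXES_PER_AREA
        and state.time_remaining >= timing.t1
    ):
        actions.append(STAY)
    for area in range(N_AREAS):
        if area == state.location or k.boxes_taken(area) >= BOXES_PER_AREA:
            continue
        cand = move(area)
        if state.time_remaining >= action_cost(state, cand, timing, first_move_cost):
            actions.append(cand)
    return actions


class OptimalSolver:
    """Memoized backward-induction solver for one subject's timing.

    One instance serves every condition (environment label × battery): the
    condition only determines the root state, built with :meth:`root_state`.
    """

    def __init__(
        self,
        timing: SubjectTiming,
        schedule: CoinSchedule = DEFAULT_SCHEDULE,
        first_move_cost: str = "t1",
    ) -> None:
        if first_move_cost not in ("t1", "t2"):
            raise ValueError("first_move_cost must be 't1' or 't2'")
        self.timing = timing
        self.schedule = schedule
        self.first_move_cost = first_move_cost
        self._first_cost = timing.t1 if first_move_cost == "t1" else timing.t2
        self._memo: dict[tuple, float] = {}

    @classmethod
    def from_task_config(
        cls, timing: SubjectTiming, task: TaskConfig
    ) -> "OptimalSolver":
        return cls(timing, schedule=task.schedule, first_move_cost=task.first_move_cost)

    # -- public state construction -------------------------------------------

    def root_state(
        self, env_label: EnvLabel | str, battery: BatteryCondition
    ) -> AgentState:
        return AgentState(
            time_remaining=battery.duration,
            knowledge=KnowledgeState.initial(env_label),
            location=CENTRAL,
        )

    def feasible_actions(self, state: AgentState) -> list[ForagingAction]:
        return feasible_actions(state, self.timing, self.first_move_cost)

    # -- compact core --------------------------------------------------------

    def _encode(self, k: KnowledgeState) -> tuple[int, ...]:
        return tuple(_code(r, b) for r, b in k.entries)

    def _seq_coins(self, code: int) -> int:
        seq = (
            self.schedule.rich_sequence
            if _is_rich(code)
            else self.schedule.poor_sequence
        )
        return seq[_boxes_of(code)]

    @staticmethod
    def _closed(entries: tuple[int, ...]) -> tuple[int, ...]:
        """Forced-inference closure on the integer encoding (mixed env)."""
        n_rich = sum(1 for c in entries if _is_rich(c))
        if n_rich == MIXED_N_RICH:
            return tuple(c if c != _UNKNOWN else _POOR0 for c in entries)
        n_poor = sum(1 for c in entries if c >= _POOR0)
        if n_poor == N_AREAS - MIXED_N_RICH:
            return tuple(c if c != _UNKNOWN else _RICH0 for c in entries)
        return entries

    def _value(self, t: float, entries: tuple[int, ...], loc: int) -> float:
        """Coins-to-go from the encoded state; the hot recursion."""
        key = (round(t / TIME_QUANTUM), entries, loc)
        memo = self._memo
        cached = memo.get(key)
        if cached is not None:
            return cached
        t1 = self.timing.t1
        best = 0.0  # terminal value; any action is worth >= 1 coin
        if loc >= 0 and t >= t1:
            code = entries[loc]  # current area is always revealed
            if code != _UNKNOWN and _boxes_of(code) < BOXES_PER_AREA:
                nxt = entries[:loc] + (code + 1,) + entries[loc + 1:]
                best = self._seq_coins(code) + self._value(t - t1, nxt, loc)
        move_cost = self._first_cost if loc == _CENTRAL_CODE else self.timing.t2
        if t >= move_cost:
            t_next = t - move_cost
            n_unknown = entries.count(_UNKNOWN)
            n_rich = sum(1 for c in entries if _is_rich(c))
            for area in range(N_AREAS):
                if area == loc:
                    continue
                code = entries[area]
                if code == _UNKNOWN:
                    p_rich = (MIXED_N_RICH - n_rich) / n_unknown
                    value = 0.0
                    if p_rich > 0.0:
                        nxt = self._closed(
                            entries[:area] + (_RICH0 + 1,) + entries[area + 1:]
                        )
                        value += p_rich * (
                            self.schedule.rich_sequence[0]
                            + self._value(t_next, nxt, area)
                        )
                    if p_rich < 1.0:
                        nxt = self._closed(
                            entries[:area] + (_POOR0 + 1,) + entries[area + 1:]
                        )
                        value += (1.0 - p_rich) * (
                            self.schedule.poor_sequence[0]
                            + self._value(t_next, nxt, area)
                        )
                else:
                    if _boxes_of(code) >= BOXES_PER_AREA:
                        continue
                    nxt = entries[:area] + (code + 1,) + entries[area + 1:]
                    value = self._seq_coins(code) + self._value(t_next, nxt, area)
                if value > best:
                    best = value
        memo[key] = best
        return best

    # -- public value/policy interface ---------------------------------------

    def successors(
        self, state: AgentState, action: ForagingAction
    ) -> list[tuple[float, int, AgentState]]:
        """Chance-node expansion: ``(probability, coins, next_state)`` list.

        Deterministic actions return a single branch with probability one;
        entering an unexplored area returns the rich/poor reveal branches
        weighted by the exact posterior.
        """
        from .belief import prob_rich_if_entered

        cost = action_cost(state, action, self.timing, self.first_move_cost)
        t_next = state.time_remaining - cost
        if t_next < 0:
            raise ValueError("infeasible action: cost exceeds remaining time")
        k = state.knowledge
        area = state.location if action.kind == "stay_collect" else action.target
        richness = k.richness_of(area)
        if richness is not AreaRichness.UNKNOWN:
            coins = self.schedule.sequence_for(richness)[k.boxes_taken(area)]
            nxt = AgentState(t_next, k.collect(area), area)
            return [(1.0, coins, nxt)]
        p_rich = prob_rich_if_entered(k, area).p_rich
        branches = []
        for prob, reveal in (
            (p_rich, AreaRichness.RICH),
            (1.0 - p_rich, AreaRichness.POOR),
        ):
            if prob == 0.0:
                continue
            coins = self.schedule.sequence_for(reveal)[0]
            nxt = AgentState(t_next, k.reveal(area, reveal).collect(area), area)
            branches.append((prob, coins, nxt))
        return branches

    def state_value(self, state: AgentState) -> float:
        """Expected coins-to-go under optimal play; zero at terminal nodes."""
        entries = self._encode(apply_closure(state.knowledge))
        loc = _CENTRAL_CODE if state.location is CENTRAL else state.location
        return self._value(state.time_remaining, entries, loc)

    def action_value(self, state: AgentState, action: ForagingAction) -> float:
        """Expected coins-to-go of taking ``action`` and playing optimally on."""
        if action not in self.feasible_actions(state):
            raise ValueError(f"action {action} infeasible in state {state}")
        return sum(
            p * (coins + self.state_value(nxt))
            for p, coins, nxt in self.successors(state, action)
        )

    def action_values(self, state: AgentState) -> list[ActionValue]:
        """Coins-to-go of every feasible action, in tie-break order."""
        return [
            ActionValue(a, self.action_value(state, a))
            for a in self.feasible_actions(state)
        ]

    def optimal_policy(self, state: AgentState) -> ForagingAction:
        """Argmax action; ties go to the earliest action in tie-break order
        (stay before moves, then moves by ascending area index)."""
        ranked = self.action_values(state)
        if not ranked:
            raise ValueError("no feasible action: terminal state")
        best = ranked[0]
        for av in ranked[1:]:
            if av.value > best.value + 1e-12:
                best = av
        return best.action

    def root_value(
        self, env_label: EnvLabel | str, battery: BatteryCondition
    ) -> float:
        """Expected total coins of the optimal agent for one condition."""
        return self.state_value(self.root_state(env_label, battery))

    def as_policy(self):
        """Adapter for the rollout module: ``(state, rng) -> action``."""

        def policy(state: AgentState, rng=None) -> ForagingAction:
            return self.optimal_policy(state)

        return policy
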