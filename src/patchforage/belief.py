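"""Exact inference over hidden area richness.

In a mixed environment the forager knows that exactly two of the four areas
are rich but not which; the layout is uniform over the six possible
arrangements.  An area's richness is revealed the moment its first box is
collected (the box displays its coin content).  Because the composition is
fixed at two rich and two poor, reveals are anti-correlated: once two areas
of the same type are known, the remaining layout is forced.  Beliefs are
therefore computed by exact enumeration of the consistent arrangements —
never sampled — which also yields the hypergeometric reveal probability
``(2 − #known-rich) / (4 − #known)`` for entering an unknown area.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from .task_model import (
    BOXES_PER_AREA,
    EMPTY,
    MIXED_N_RICH,
    N_AREAS,
    AreaRichness,
    CoinSchedule,
    DEFAULT_SCHEDULE,
    EnvironmentConfig,
    EnvLabel,
    next_box_coins,
)


@dataclass(frozen=True)
class RevealDistribution:
    """Probability that entering a given unknown area reveals it as rich."""

    p_rich: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_rich <= 1.0:
            raise ValueError(f"p_rich out of [0, 1]: {self.p_rich}")


@dataclass(frozen=True)
class KnowledgeState:
    """What the forager can know mid-trial.

    ``entries`` holds one ``(richness, boxes_taken)`` pair per area; richness
    is ``UNKNOWN`` until the area's first collection (or until it becomes
    inferable, see :func:`apply_closure`).  The environment label itself is
    always known via the sensor.
    """

    env_label: EnvLabel
    entries: tuple[tuple[AreaRichness, int], ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_AREAS:
            raise ValueError(f"expected {N_AREAS} area entries")
        for richness, taken in self.entries:
            if not 0 <= taken <= BOXES_PER_AREA:
                raise ValueError(f"boxes_taken out of range: {taken}")
            if richness is AreaRichness.UNKNOWN and taken != 0:
                raise ValueError("an area is revealed on its first collection")
        if self.env_label is EnvLabel.MIXED:
            n_rich = self.n_revealed(AreaRichness.RICH)
            n_poor = self.n_revealed(AreaRichness.POOR)
            if n_rich > MIXED_N_RICH or n_poor > N_AREAS - MIXED_N_RICH:
                raise ValueError("more same-type areas than the composition allows")

    @classmethod
    def initial(cls, env_label: EnvLabel | str) -> "KnowledgeState":
        """Knowledge at trial start: everything unknown, then closure.

        In a rich environment closure immediately labels all areas rich.
        """
        env_label = EnvLabel(env_label) if not isinstance(env_label, EnvLabel) else env_label
        blank = cls(env_label, ((AreaRichness.UNKNOWN, 0),) * N_AREAS)
        return apply_closure(blank)

    def n_revealed(self, richness: AreaRichness) -> int:
        return sum(r is richness for r, _ in self.entries)

    def richness_of(self, area: int) -> AreaRichness:
        return self.entries[area][0]

    def boxes_taken(self, area: int) -> int:
        return self.entries[area][1]

    def reveal(self, area: int, richness: AreaRichness) -> "KnowledgeState":
        """Record the observed richness of an area (closure applied)."""
        if richness is AreaRichness.UNKNOWN:
            raise ValueError("cannot reveal an area as unknown")
        current, taken = self.entries[area]
        if current is not AreaRichness.UNKNOWN and current is not richness:
            raise ValueError(f"area {area} already revealed as {current.value}")
        entries = list(self.entries)
        entries[area] = (richness, taken)
        return apply_closure(KnowledgeState(self.env_label, tuple(entries)))

    def collect(self, area: int) -> "KnowledgeState":
        """Record one more box taken in an already-revealed area."""
        richness, taken = self.entries[area]
        if richness is AreaRichness.UNKNOWN:
            raise ValueError("collecting reveals an area; call reveal() first")
        if taken >= BOXES_PER_AREA:
            raise ValueError(f"area {area} is exhausted")
        entries = list(self.entries)
        entries[area] = (richness, taken + 1)
        return KnowledgeState(self.env_label, tuple(entries))

    def to_tuple_string(self, schedule: CoinSchedule = DEFAULT_SCHEDULE) -> str:
        """Compact display form listing each area's next-box coin value.

        Unknown areas print ``?`` and exhausted areas ``-``; e.g.
        ``"(7, 4, ?, ?)"``.
        """
        parts = []
        for richness, taken in self.entries:
            if richness is AreaRichness.UNKNOWN:
                parts.append("?")
            else:
                coins = next_box_coins(richness, taken, schedule)
                parts.append("-" if coins == EMPTY else str(coins))
        return "(" + ", ".join(parts) + ")"


def apply_closure(k: KnowledgeState) -> KnowledgeState:
    """Fill in every richness that is logically forced by what is known.

    In a rich environment all areas are rich.  In a mixed environment, once
    two rich (resp. poor) areas are revealed the remaining unknowns must be
    poor (resp. rich).  Idempotent; never alters a revealed entry.
    """
    entries = list(k.entries)
    if k.env_label is EnvLabel.RICH:
        entries = [(AreaRichness.RICH, taken) for _, taken in entries]
        return KnowledgeState(k.env_label, tuple(entries))
    n_rich = k.n_revealed(AreaRichness.RICH)
    n_poor = k.n_revealed(AreaRichness.POOR)
    forced: AreaRichness | None = None
    if n_rich == MIXED_N_RICH:
        forced = AreaRichness.POOR
    elif n_poor == N_AREAS - MIXED_N_RICH:
        forced = AreaRichness.RICH
    if forced is not None:
        entries = [
            (forced, taken) if richness is AreaRichness.UNKNOWN else (richness, taken)
            for richness, taken in entries
        ]
    return KnowledgeState(k.env_label, tuple(entries))


def uncertainty_resolved(k: KnowledgeState) -> bool:
    """True once the full rich/poor layout is known or inferable.

    Always true in a rich environment; in a mixed environment true exactly
    when two same-type areas have been revealed (closure then fixes the rest).
    """
    return all(
        r is not AreaRichness.UNKNOWN for r, _ in apply_closure(k).entries
    )


def consistent_configs(k: KnowledgeState) -> list[tuple[EnvironmentConfig, float]]:
    """All environment layouts consistent with the knowledge state.

    Returns ``(config, posterior probability)`` pairs; the prior is uniform
    over arrangements, so the posterior is uniform over the consistent ones.
    """
    if k.env_label is EnvLabel.RICH:
        return [(EnvironmentConfig.all_rich(), 1.0)]
    configs = []
    for rich_areas in itertools.combinations(range(N_AREAS), MIXED_N_RICH):
        candidate = EnvironmentConfig.mixed(rich_areas)
        ok = all(
            known is AreaRichness.UNKNOWN or known is candidate.area_richness[area]
            for area, (known, _) in enumerate(k.entries)
        )
        if ok:
            configs.append(candidate)
    if not configs:
        raise ValueError("knowledge state admits no environment layout")
    p = 1.0 / len(configs)
    return [(c, p) for c in configs]


def prob_rich_if_entered(k: KnowledgeState, area: int) -> RevealDistribution:
    """Posterior probability that an unexplored area turns out rich.

    Uniform sampling of two rich areas out of four makes this the
    hypergeometric ratio ``(2 − #revealed-rich) / (4 − #revealed)``; with one
    rich and one poor area known the remaining two are a coin flip.
    """
    if k.env_label is EnvLabel.RICH:
        raise ValueError("nothing is unknown in a rich environment")
    if k.richness_of(area) is not AreaRichness.UNKNOWN:
        raise ValueError(f"area {area} is already revealed")
    n_rich = k.n_revealed(AreaRichness.RICH)
    n_known = N_AREAS - k.n_revealed(AreaRichness.UNKNOWN)
    return RevealDistribution(p_rich=(MIXED_N_RICH - n_rich) / (N_AREAS - n_known))
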