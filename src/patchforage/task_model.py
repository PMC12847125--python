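"""Fixed structure of the patch-foraging task.

The task world is a central zone surrounded by four areas (indexed 0..3 in
the fixed order north, east, south, west).  Each area holds five sequentially
collectable boxes whose coin content depletes linearly: a *rich* area pays
8, 7, 6, 5, 4 coins, a *poor* area pays 5, 4, 3, 2, 1.  A trial is either a
*rich environment* (all four areas rich) or a *mixed environment* (exactly
two rich and two poor, placed uniformly at random).  Foraging time is capped
by a battery of 50 s (long) or 25 s (short).  Moving costs are abstracted
into two per-subject durations: ``T1`` to collect the next box within the
current area and ``T2`` to leave, travel to another area and collect its
first box there.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

N_AREAS = 4
BOXES_PER_AREA = 5
#: number of rich areas in a mixed environment (the rest are poor)
MIXED_N_RICH = 2

#: sentinel returned by :func:`next_box_coins` when an area is exhausted
EMPTY = "empty"


class AreaRichness(enum.Enum):
    """Richness of one area; ``UNKNOWN`` is legal only in a knowledge state."""

    RICH = "rich"
    POOR = "poor"
    UNKNOWN = "unknown"


class EnvLabel(enum.Enum):
    """Global environment label, always known to the forager via the sensor."""

    RICH = "rich_env"
    MIXED = "mixed_env"


class BatteryLabel(enum.Enum):
    LONG = "long"
    SHORT = "short"


BATTERY_DURATIONS = {BatteryLabel.LONG: 50.0, BatteryLabel.SHORT: 25.0}


@dataclass(frozen=True)
class CoinSchedule:
    """Per-box coin payout, in collection order, for rich and poor areas."""

    rich_sequence: tuple[int, ...] = (8, 7, 6, 5, 4)
    poor_sequence: tuple[int, ...] = (5, 4, 3, 2, 1)

    def __post_init__(self) -> None:
        if len(self.rich_sequence) != len(self.poor_sequence):
            raise ValueError("rich and poor sequences must have equal length")
        if not self.rich_sequence:
            raise ValueError("coin sequences must be non-empty")

    @property
    def boxes_per_area(self) -> int:
        return len(self.rich_sequence)

    def sequence_for(self, richness: AreaRichness) -> tuple[int, ...]:
        if richness is AreaRichness.RICH:
            return self.rich_sequence
        if richness is AreaRichness.POOR:
            return self.poor_sequence
        raise ValueError("no coin sequence for unknown richness")

    def area_total(self, richness: AreaRichness) -> int:
        return sum(self.sequence_for(richness))


DEFAULT_SCHEDULE = CoinSchedule()


@dataclass(frozen=True)
class SubjectTiming:
    """Per-subject action durations in seconds.

    ``t1`` is the within-area collection time, ``t2`` the leave-travel-collect
    time for switching areas.  Switching is slower by construction.
    """

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError(f"T1 must be positive, got {self.t1}")
        if not self.t2 > self.t1:
            raise ValueError(f"T2 must exceed T1, got T1={self.t1}, T2={self.t2}")


#: population-average timing reported for the study cohort
MEAN_TIMING = SubjectTiming(t1=3.41, t2=6.10)


@dataclass(frozen=True)
class BatteryCondition:
    label: BatteryLabel
    duration: float

    def __post_init__(self) -> None:
        expected = BATTERY_DURATIONS[self.label]
        if self.duration != expected:
            raise ValueError(
                f"{self.label.value} battery lasts {expected} s, got {self.duration}"
            )

    @classmethod
    def from_label(cls, label: BatteryLabel | str) -> "BatteryCondition":
        label = BatteryLabel(label) if not isinstance(label, BatteryLabel) else label
        return cls(label=label, duration=BATTERY_DURATIONS[label])


LONG_BATTERY = BatteryCondition.from_label(BatteryLabel.LONG)
SHORT_BATTERY = BatteryCondition.from_label(BatteryLabel.SHORT)


@dataclass(frozen=True)
class EnvironmentConfig:
    """Hidden truth of one trial: the richness of each area plus the label."""

    area_richness: tuple[AreaRichness, ...]
    label: EnvLabel

    def __post_init__(self) -> None:
        if len(self.area_richness) != N_AREAS:
            raise ValueError(f"expected {N_AREAS} areas")
        if any(r is AreaRichness.UNKNOWN for r in self.area_richness):
            raise ValueError("environment truth cannot contain unknown areas")
        n_rich = sum(r is AreaRichness.RICH for r in self.area_richness)
        if self.label is EnvLabel.RICH and n_rich != N_AREAS:
            raise ValueError("rich environment must have all areas rich")
        if self.label is EnvLabel.MIXED and n_rich != MIXED_N_RICH:
            raise ValueError(
                f"mixed environment must have exactly {MIXED_N_RICH} rich areas"
            )

    @classmethod
    def all_rich(cls) -> "EnvironmentConfig":
        return cls((AreaRichness.RICH,) * N_AREAS, EnvLabel.RICH)

    @classmethod
    def mixed(cls, rich_areas: Sequence[int]) -> "EnvironmentConfig":
        rich = frozenset(rich_areas)
        if len(rich) != MIXED_N_RICH:
            raise ValueError(f"need exactly {MIXED_N_RICH} rich areas")
        richness = tuple(
            AreaRichness.RICH if a in rich else AreaRichness.POOR
            for a in range(N_AREAS)
        )
        return cls(richness, EnvLabel.MIXED)


def next_box_coins(
    richness: AreaRichness,
    boxes_taken: int,
    schedule: CoinSchedule = DEFAULT_SCHEDULE,
) -> int | str:
    """Coins delivered by the next box of an area, or ``EMPTY`` if exhausted.

    ``boxes_taken`` is the number of boxes already collected in that area, so
    the first collection of a rich area (``boxes_taken=0``) pays 8 coins and
    the fifth collection of a poor area (``boxes_taken=4``) pays 1.
    """
    if richness is AreaRichness.UNKNOWN:
        raise ValueError(
            "cannot give coins for an unknown area; marginalize over beliefs"
        )
    if not 0 <= boxes_taken <= schedule.boxes_per_area:
        raise ValueError(f"boxes_taken out of range: {boxes_taken}")
    if boxes_taken == schedule.boxes_per_area:
        return EMPTY
    return schedule.sequence_for(richness)[boxes_taken]


def sample_environment(label: EnvLabel | str, rng: np.random.Generator) -> EnvironmentConfig:
    """Draw the hidden area layout for a trial.

    A rich environment is forced (all areas rich); in a mixed environment the
    two rich areas are placed uniformly among the six possible arrangements.
    """
    label = EnvLabel(label) if not isinstance(label, EnvLabel) else label
    if label is EnvLabel.RICH:
        return EnvironmentConfig.all_rich()
    rich_areas = rng.choice(N_AREAS, size=MIXED_N_RICH, replace=False)
    return EnvironmentConfig.mixed(rich_areas.tolist())


def total_coins_available(
    config: EnvironmentConfig, schedule: CoinSchedule = DEFAULT_SCHEDULE
) -> int:
    """Sum of all coins obtainable if every box in every area were collected."""
    return sum(schedule.area_total(r) for r in config.area_richness)


@dataclass(frozen=True)
class TaskConfig:
    """Serializable bundle of the task's fixed parameters.

    Defaults are the published task; individual entries can be overridden
    (e.g. alternative coin schedules) for sensitivity analyses.  The area
    count and mixed-environment composition are structural and fixed.
    """

    schedule: CoinSchedule = DEFAULT_SCHEDULE
    long_battery_s: float = 50.0
    short_battery_s: float = 25.0
    n_areas: int = N_AREAS
    first_move_cost: str = "t1"  # cost of entering the first area from the central zone

    def __post_init__(self) -> None:
        if self.n_areas != N_AREAS:
            raise ValueError("the task has exactly four areas")
        if self.first_move_cost not in ("t1", "t2"):
            raise ValueError("first_move_cost must be 't1' or 't2'")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "rich_sequence": list(self.schedule.rich_sequence),
            "poor_sequence": list(self.schedule.poor_sequence),
            "long_battery_s": self.long_battery_s,
            "short_battery_s": self.short_battery_s,
            "n_areas": self.n_areas,
            "first_move_cost": self.first_move_cost,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            schedule=CoinSchedule(
                rich_sequence=tuple(payload["rich_sequence"]),
                poor_sequence=tuple(payload["poor_sequence"]),
            ),
            long_battery_s=float(payload["long_battery_s"]),
            short_battery_s=float(payload["short_battery_s"]),
            n_areas=int(payload.get("n_areas", N_AREAS)),
            first_move_cost=str(payload.get("first_move_cost", "t1")),
        )


DEFAULT_TASK = TaskConfig()
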