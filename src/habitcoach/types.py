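"""Shared domain types for the coaching decision-support engine.

The engine's vocabulary: children carry anthropometric records and weekly
questionnaire responses; every monitored behaviour variable is stratified
into a traffic-light flag (green = optimal, maintain; yellow = not optimal,
change; red = needs immediate change, prioritised); weekly plans assign one
mission per health-behaviour dimension.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class FlagStatus(enum.IntEnum):
    """Traffic-light status of one behaviour. Ordered by severity: red > yellow > green."""

    green = 0
    yellow = 1
    red = 2

    def __str__(self) -> str:  # serialised as the colour name
        return self.name


class NutritionalStatus(str, enum.Enum):
    """Five-level BMI-for-age categorisation, ordered by z-score."""

    severe_thinness = "severe_thinness"
    thinness = "thinness"
    normal = "normal"
    overweight = "overweight"
    obesity = "obesity"


#: NutritionalStatus members in increasing z order.
STATUS_ORDER: tuple[NutritionalStatus, ...] = (
    NutritionalStatus.severe_thinness,
    NutritionalStatus.thinness,
    NutritionalStatus.normal,
    NutritionalStatus.overweight,
    NutritionalStatus.obesity,
)


class Dimension(str, enum.Enum):
    """The three health-behaviour dimensions a weekly plan covers."""

    physical_activity_sleep = "physical_activity_sleep"
    diet = "diet"
    education_empowerment = "education_empowerment"


class Ability(str, enum.Enum):
    """Gamified-app abilities earned by completing missions."""

    dexterity = "dexterity"
    discipline = "discipline"
    intelligence = "intelligence"


class Instrument(str, enum.Enum):
    ffq = "ffq"
    paqc = "paqc"
    agent_report = "agent_report"


@dataclass(frozen=True)
class ChildProfile:
    child_id: str
    sex: Sex
    birth_date: dt.date
    pilot_site: str | None = None

    def age_months(self, on: dt.date) -> int:
        """Completed age in months on a given date."""
        if on <= self.birth_date:
            raise ValueError(
                f"record date {on} not after birth date {self.birth_date}"
            )
        months = (on.year - self.birth_date.year) * 12 + (on.month - self.birth_date.month)
        if on.day < self.birth_date.day:
            months -= 1
        return months


@dataclass(frozen=True)
class AnthropometricRecord:
    child_id: str
    date: dt.date
    weight_kg: float
    height_m: float
    waist_cm: float | None = None
    hip_cm: float | None = None
    fat_mass_pct: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"weight must be positive, got {self.weight_kg}")
        if self.height_m <= 0:
            raise ValueError(f"height must be positive, got {self.height_m}")
        if self.fat_mass_pct is not None and not (0 <= self.fat_mass_pct <= 100):
            raise ValueError(f"fat_mass_pct must be in [0, 100], got {self.fat_mass_pct}")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One child-week response to one instrument.

    Item values are instrument-specific: PAQ-C items are integers 1-5, the
    food-frequency questionnaire carries category strings, and the weekly
    6-item agent report carries 0/1 (unhealthy/healthy) answers.
    """

    child_id: str
    week_id: str  # ISO week, "YYYY-Www"
    instrument: Instrument
    items: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        if self.instrument is Instrument.agent_report and len(self.items) != 6:
            raise ValueError(
                f"agent report must have exactly 6 items, got {len(self.items)}"
            )
        if self.instrument is Instrument.paqc:
            for item_id, value in self.items:
                if value not in (1, 2, 3, 4, 5):
                    raise ValueError(
                        f"PAQ-C item {item_id!r} must be an integer 1-5, got {value!r}"
                    )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.items)


def iso_week(d: dt.date) -> str:
    y, w, _ = d.isocalendar()
    return f"{y}-W{w:02d}"


def next_iso_week(week_id: str) -> str:
    """The ISO week following ``week_id`` (handles year rollover)."""
    year, week = int(week_id[:4]), int(week_id[6:])
    monday = dt.date.fromisocalendar(year, week, 1) + dt.timedelta(weeks=1)
    return iso_week(monday)


@dataclass
class FlagHistory:
    """Per-behaviour weekly flag record, oldest week first."""

    behaviour_id: str
    weeks: list[str] = field(default_factory=list)
    flags: list[FlagStatus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.weeks) != len(self.flags):
            raise ValueError("weeks and flags must have the same length")
        if any(a >= b for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")

    def append(self, week_id: str, flag: FlagStatus) -> None:
        if self.weeks and week_id <= self.weeks[-1]:
            raise ValueError(f"week {week_id} not after {self.weeks[-1]}")
        self.weeks.append(week_id)
        self.flags.append(flag)

    def trailing_red_run(self) -> int:
        """Consecutive red flags ending at the most recent recorded week."""
        n = 0
        for flag in reversed(self.flags):
            if flag is not FlagStatus.red:
                break
            n += 1
        return n
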