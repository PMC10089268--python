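"""The weekly coaching decision support proper.

Every week each child's self-reports (food-frequency questionnaire, PAQ-C,
6-item agent report) and wearable summaries are stratified into one
green/yellow/red flag per behaviour. For each of the three health-behaviour
dimensions (physical activity & sleep, diet, education & empowerment) the
engine selects the behaviour most in need of change — red before yellow
before green, ties broken by the longest run of consecutive red flags ending
at the current week, remaining ties by the configured behaviour order — and
assigns a mission from the catalogue targeting it. Carers validate mission
completion; completed missions earn points split across the three
gamified-app abilities (dexterity, discipline, intelligence); stalled
missions and unhealthy trend verdicts trigger motivation messages.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

from .health import (
    StratificationRule,
    map_ffq_frequency,
    score_paqc,
    stratify_variable,
)
from .risk import RiskDetectionResult, Verdict
from .types import (
    Ability,
    Dimension,
    FlagHistory,
    FlagStatus,
    Instrument,
    QuestionnaireResponse,
    next_iso_week,
)

logger = logging.getLogger(__name__)


class Behaviour(BaseModel):
    """One coachable behaviour, e.g. P2 'Increase active minutes'."""

    behaviour_id: str
    label: str
    dimension: Dimension
    source_variables: list[str]
    rule: StratificationRule


class MissionMode(str, enum.Enum):
    individual = "individual"
    social = "social"


class Mission(BaseModel):
    mission_id: int = Field(gt=0)
    dimension: Dimension
    target_behaviour_id: str
    description: str = ""
    mode: MissionMode = MissionMode.individual
    points: int = Field(default=10, ge=0)
    ability: Ability = Ability.discipline


class Catalogue(BaseModel):
    """Mission catalogue; validates that missions target behaviours of their own dimension."""

    missions: list[Mission]
    behaviours: list[Behaviour]

    @model_validator(mode="after")
    def _consistent(self) -> "Catalogue":
        dims = {b.behaviour_id: b.dimension for b in self.behaviours}
        ids = [m.mission_id for m in self.missions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mission ids in catalogue")
        for m in self.missions:
            if m.target_behaviour_id not in dims:
                raise ValueError(
                    f"mission {m.mission_id} targets unknown behaviour {m.target_behaviour_id!r}"
                )
            if dims[m.target_behaviour_id] != m.dimension:
                raise ValueError(
                    f"mission {m.mission_id} ({m.dimension.value}) targets behaviour "
                    f"{m.target_behaviour_id!r} of dimension {dims[m.target_behaviour_id].value}"
                )
        return self

    def behaviour_order(self, dimension: Dimension) -> list[str]:
        """Configured priority order: behaviours as listed in the config."""
        return [b.behaviour_id for b in self.behaviours if b.dimension == dimension]


@dataclass(frozen=True)
class CoachingPlan:
    child_id: str
    week_id: str  # the week the plan applies to (the week after assessment)
    missions: tuple[Mission, ...]
    rationale: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.missions) != 3:
            raise ValueError(f"plan must hold exactly 3 missions, got {len(self.missions)}")
        dims = {m.dimension for m in self.missions}
        if len(dims) != 3:
            raise ValueError("plan must hold one mission per dimension")

    def mission_for(self, dimension: Dimension) -> Mission:
        return next(m for m in self.missions if m.dimension == dimension)


class OutcomeStatus(str, enum.Enum):
    completed = "completed"
    not_completed = "not_completed"
    pending = "pending"


class Validator(str, enum.Enum):
    family = "family"
    educator = "educator"
    none = "none"


@dataclass(frozen=True)
class MissionOutcome:
    mission_id: int
    child_id: str
    week_id: str
    status: OutcomeStatus
    validated_by: Validator

    def __post_init__(self) -> None:
        if self.status is not OutcomeStatus.pending and self.validated_by is Validator.none:
            raise ValueError(f"{self.status.value} outcome requires a validator")


@dataclass(frozen=True)
class CarerFeedback:
    """One carer's report on an assigned mission."""

    mission_id: int
    child_id: str
    week_id: str
    completed: bool
    reporter: Validator


@dataclass(frozen=True)
class PointsLedger:
    total: int
    ability_pct: Mapping[Ability, float]  # percentages, sum to 100 when total > 0


@dataclass(frozen=True)
class MotivationMessage:
    child_id: str
    week_id: str
    kind: str  # "stalled_mission" | "risk_alert"
    dimension: Dimension
    text: str
    mission_id: int | None = None


DEFAULT_MESSAGE_TEMPLATES = {
    "stalled_mission": "Keep going! Your mission '{description}' is waiting for you this week.",
    "risk_alert": "Your {variable} has been heading the wrong way — your missions can turn it around!",
}


# ---------------------------------------------------------------------------
# weekly assessment

def resolve_variables(
    reports: Iterable[QuestionnaireResponse],
    wearable_summary: Mapping[str, float],
    ffq_mapping: Mapping[str, float] | None = None,
    paqc_items: int = 9,
) -> dict[str, float]:
    """Flatten one child-week of inputs into a variable -> value map.

    Wearable summaries pass through under their own variable ids. FFQ items
    become weekly frequencies under their item ids; the PAQ-C composite is
    exposed as ``paqc_score``; the agent report as ``agent_report_score``
    (count of healthy answers, 0-6).
    """
    values: dict[str, float] = dict(wearable_summary)
    for report in reports:
        if report.instrument is Instrument.ffq:
            for item_id, category in report.items:
                values[item_id] = map_ffq_frequency(str(category), ffq_mapping)
        elif report.instrument is Instrument.paqc:
            scores = [int(v) for _, v in report.items]
            values["paqc_score"] = score_paqc(scores, n_items=paqc_items)
        elif report.instrument is Instrument.agent_report:
            values["agent_report_score"] = float(sum(int(v) for _, v in report.items))
    return values


def assess_weekly_flags(
    reports: Sequence[QuestionnaireResponse],
    wearable_summary: Mapping[str, float],
    behaviours: Sequence[Behaviour],
    ffq_mapping: Mapping[str, float] | None = None,
    missing_policy: str = "yellow",
) -> dict[str, FlagStatus]:
    """One flag per behaviour from this week's reports and wearable summaries.

    A behaviour spanning several source variables takes its most severe
    flag. Behaviours with no resolvable data are flagged per the missing-data
    policy: ``"yellow"`` (default, logged) or ``"strict"`` (error).
    """
    values = resolve_variables(reports, wearable_summary, ffq_mapping)
    flags: dict[str, FlagStatus] = {}
    for behaviour in behaviours:
        available = [v for v in behaviour.source_variables if v in values]
        if not available:
            if missing_policy == "strict":
                raise ValueError(
                    f"behaviour {behaviour.behaviour_id}: no data for any of "
                    f"{behaviour.source_variables}"
                )
            logger.warning(
                "behaviour %s: no data for %s; flagged yellow by missing-data policy",
                behaviour.behaviour_id, behaviour.source_variables,
            )
            flags[behaviour.behaviour_id] = FlagStatus.yellow
            continue
        flag = max(stratify_variable(values[v], behaviour.rule) for v in available)
        flags[behaviour.behaviour_id] = flag
        logger.info("behaviour %s -> %s", behaviour.behaviour_id, flag)
    return flags


# ---------------------------------------------------------------------------
# mission selection

def _red_run_key(
    behaviour_id: str,
    current: FlagStatus,
    histories: Mapping[str, FlagHistory],
) -> int:
    """Length of the consecutive red run ending at the current week."""
    if current is not FlagStatus.red:
        return 0
    past = histories.get(behaviour_id)
    return 1 + (past.trailing_red_run() if past is not None else 0)


def select_mission_for_dimension(
    flags: Mapping[str, FlagStatus],
    histories: Mapping[str, FlagHistory] | Sequence[FlagHistory],
    catalogue: Catalogue,
    dimension: Dimension,
) -> Mission:
    """The one mission for a dimension this week.

    Priority: most severe current flag (red > yellow > green); ties broken by
    the longest run of consecutive red flags ending at the most recent week
    (the behaviour "remaining most recently in red status" wins); remaining
    ties by the configured behaviour order. All-green dimensions still get a
    mission — the first behaviour in configured order, as maintenance.
    """
    if not isinstance(histories, Mapping):
        histories = {h.behaviour_id: h for h in histories}
    order = catalogue.behaviour_order(dimension)
    candidates = [b for b in order if b in flags]
    if not candidates:
        raise ValueError(f"no flagged behaviours for dimension {dimension.value}")
    targeted = {m.target_behaviour_id for m in catalogue.missions if m.dimension == dimension}
    candidates = [b for b in candidates if b in targeted]
    if not candidates:
        raise ValueError(f"catalogue has no missions for dimension {dimension.value}")

    def key(behaviour_id: str) -> tuple:
        return (
            -int(flags[behaviour_id]),
            -_red_run_key(behaviour_id, flags[behaviour_id], histories),
            order.index(behaviour_id),
        )

    chosen = min(candidates, key=key)
    mission = min(
        (m for m in catalogue.missions if m.target_behaviour_id == chosen),
        key=lambda m: m.mission_id,
    )
    logger.info(
        "dimension %s: behaviour %s (flag %s, red run %d) -> mission %d",
        dimension.value, chosen, flags[chosen],
        _red_run_key(chosen, flags[chosen], histories), mission.mission_id,
    )
    return mission


def generate_coaching_plan(
    child_id: str,
    week_id: str,
    flags: Mapping[str, FlagStatus],
    histories: Mapping[str, FlagHistory] | Sequence[FlagHistory],
    catalogue: Catalogue,
) -> CoachingPlan:
    """Weekly plan: exactly one mission per dimension, applying to the week
    after the assessed one."""
    missions = tuple(
        select_mission_for_dimension(flags, histories, catalogue, dim)
        for dim in Dimension
    )
    dims = {b.behaviour_id: b.dimension for b in catalogue.behaviours}
    rationale = {
        b: f"{dims[b].value}:{flags[b]}" for b in flags if b in dims
    }
    return CoachingPlan(
        child_id=child_id,
        week_id=next_iso_week(week_id),
        missions=missions,
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# validation, points, motivation

def validate_mission(
    feedback: CarerFeedback,
    plan: CoachingPlan,
) -> MissionOutcome:
    """Turn carer feedback on an assigned mission into a validated outcome."""
    if feedback.mission_id not in {m.mission_id for m in plan.missions}:
        raise ValueError(
            f"mission {feedback.mission_id} was not assigned to {plan.child_id} "
            f"in week {plan.week_id}"
        )
    if feedback.reporter is Validator.none:
        raise ValueError("feedback must identify the reporting carer")
    return MissionOutcome(
        mission_id=feedback.mission_id,
        child_id=feedback.child_id,
        week_id=feedback.week_id,
        status=OutcomeStatus.completed if feedback.completed else OutcomeStatus.not_completed,
        validated_by=feedback.reporter,
    )


def resolve_outcomes(
    plan: CoachingPlan,
    feedback: Sequence[CarerFeedback],
    deadline_passed: bool = False,
) -> list[MissionOutcome]:
    """Outcomes for every mission of a plan.

    Conflicting reports are resolved educator-over-family (logged); missions
    without feedback stay pending until the deadline (end of the following
    week), after which they count as not completed.
    """
    authority = {Validator.educator: 2, Validator.family: 1}
    outcomes = []
    for mission in plan.missions:
        reports = [f for f in feedback if f.mission_id == mission.mission_id]
        if reports:
            best = max(reports, key=lambda f: authority.get(f.reporter, 0))
            if len({f.completed for f in reports}) > 1:
                logger.warning(
                    "mission %d: conflicting carer reports, keeping %s's",
                    mission.mission_id, best.reporter.value,
                )
            outcomes.append(validate_mission(best, plan))
        elif deadline_passed:
            outcomes.append(
                MissionOutcome(
                    mission.mission_id, plan.child_id, plan.week_id,
                    OutcomeStatus.not_completed, Validator.educator,
                )
            )
        else:
            outcomes.append(
                MissionOutcome(
                    mission.mission_id, plan.child_id, plan.week_id,
                    OutcomeStatus.pending, Validator.none,
                )
            )
    return outcomes


def award_points(
    outcomes: Sequence[MissionOutcome], catalogue: Catalogue
) -> PointsLedger:
    """Total points of completed missions and the ability percentage split."""
    by_id = {m.mission_id: m for m in catalogue.missions}
    totals = {ability: 0 for ability in Ability}
    for outcome in outcomes:
        if outcome.status is not OutcomeStatus.completed:
            continue
        mission = by_id.get(outcome.mission_id)
        if mission is None:
            raise ValueError(f"outcome references unknown mission {outcome.mission_id}")
        totals[mission.ability] += mission.points
    total = sum(totals.values())
    if total == 0:
        return PointsLedger(0, {a: 0.0 for a in Ability})
    return PointsLedger(total, {a: 100.0 * v / total for a, v in totals.items()})


def trigger_motivation(
    plan: CoachingPlan,
    progress: Mapping[int, bool],
    risks: Sequence[RiskDetectionResult] = (),
    templates: Mapping[str, str] | None = None,
    variable_dimensions: Mapping[str, Dimension] | None = None,
) -> list[MotivationMessage]:
    """Mid-week nudges: one message per stalled mission and per unhealthy
    trend verdict. Deterministic and idempotent within a week."""
    templates = dict(DEFAULT_MESSAGE_TEMPLATES, **(templates or {}))
    messages = []
    for mission in plan.missions:
        if not progress.get(mission.mission_id, False):
            messages.append(
                MotivationMessage(
                    child_id=plan.child_id,
                    week_id=plan.week_id,
                    kind="stalled_mission",
                    dimension=mission.dimension,
                    mission_id=mission.mission_id,
                    text=templates["stalled_mission"].format(description=mission.description),
                )
            )
    var_dims = variable_dimensions or {}
    for risk in risks:
        if risk.verdict is Verdict.no_risk:
            continue
        dimension = var_dims.get(risk.variable_id, Dimension.physical_activity_sleep)
        messages.append(
            MotivationMessage(
                child_id=plan.child_id,
                week_id=plan.week_id,
                kind="risk_alert",
                dimension=dimension,
                text=templates["risk_alert"].format(variable=risk.variable_id),
            )
        )
    return messages


DEFAULT_AGENT_REPORT_ITEMS = (
    ("ar1", "Did you eat fruit every day this week?"),
    ("ar2", "Did you eat vegetables every day this week?"),
    ("ar3", "Did you avoid sugary drinks and sweets most days?"),
    ("ar4", "Were you active for at least one hour most days?"),
    ("ar5", "Did you play outside or do sport with friends or family?"),
    ("ar6", "Did you go to bed on time most nights?"),
)


def build_agent_report(
    child_id: str,
    week_id: str,
    items: Sequence[tuple[str, str]] | None = None,
    strict: bool = True,
) -> QuestionnaireResponse:
    """Weekly 6-question self-report template (answers initialised to 0).

    The agent report asks about the previous week's food intake and physical
    activity; its healthy-answer count feeds the education & empowerment flag.
    """
    items = DEFAULT_AGENT_REPORT_ITEMS if items is None else tuple(items)
    if strict and len(items) != 6:
        raise ValueError(f"agent report must define exactly 6 items, got {len(items)}")
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("agent report item ids must be unique")
    return QuestionnaireResponse(
        child_id=child_id,
        week_id=week_id,
        instrument=Instrument.agent_report,
        items=tuple((item_id, 0) for item_id, _ in items),
    )
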