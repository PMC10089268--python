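"""File formats, configuration and cohort reporting.

Flat-file conventions: comma-separated UTF-8 CSV with a required header and
ISO-8601 dates for tabular data (wearable days, anthropometrics, flag
histories, the LMS reference); JSON for nested records (questionnaires,
plans, outcomes, reports); YAML or JSON for configuration. Week identifiers
are ISO-8601 weeks ("YYYY-Www"). All writes are atomic (write to a
temporary file in the target directory, then rename), so a validation
failure never leaves a partial output behind.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .coaching import (
    Behaviour,
    Catalogue,
    CoachingPlan,
    Mission,
    MissionOutcome,
    OutcomeStatus,
    Validator,
)
from .data import default_config_text, load_default_lms
from .health import DEFAULT_FFQ_MAPPING, LMSTable
from .risk import DailyTimeSeries, DetectorConfig
from .types import (
    AnthropometricRecord,
    ChildProfile,
    FlagHistory,
    FlagStatus,
    Instrument,
    NutritionalStatus,
    QuestionnaireResponse,
    STATUS_ORDER,
    Sex,
)

logger = logging.getLogger(__name__)

WEARABLE_VARIABLES = ("steps", "active_minutes", "sleep_minutes", "calories")


class ValidationError(ValueError):
    """Input file failed validation; message lists the offending rows."""


# ---------------------------------------------------------------------------
# engine configuration

class Policies(BaseModel):
    missing_data: str = "yellow"
    validation_deadline_weeks: int = Field(default=1, ge=1)


class EngineConfig(BaseModel):
    """Everything the engine needs: rules, catalogue, detector tuning, paths."""

    seed: int = 0
    lms_table: str | None = None
    policies: Policies = Field(default_factory=Policies)
    ffq_mapping: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FFQ_MAPPING)
    )
    behaviours: list[Behaviour]
    missions: list[Mission]
    detector: dict[str, DetectorConfig] = Field(default_factory=dict)
    agent_report_items: list[tuple[str, str]] = Field(default_factory=list)

    def catalogue(self) -> Catalogue:
        return Catalogue(missions=self.missions, behaviours=self.behaviours)

    def load_lms(self) -> LMSTable:
        if self.lms_table is None:
            return load_default_lms()
        path = Path(self.lms_table)
        if not path.exists():
            raise ValidationError(f"LMS table not found: {path}")
        return LMSTable.from_csv(path)


def load_config(path: str | Path | None = None) -> EngineConfig:
    """Load the engine configuration from YAML/JSON, or the bundled default."""
    if path is None:
        raw = yaml.safe_load(default_config_text())
    else:
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return EngineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# atomic writes

def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# wearable CSV

def _parse_date(value: str, line: int, errors: list[str]) -> dt.date | None:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        errors.append(f"line {line}: invalid ISO date {value!r}")
        return None


def read_wearable_csv(path: str | Path) -> list[DailyTimeSeries]:
    """Read a wearable CSV into one daily series per child x variable.

    Expected header: child_id,date plus any of steps,active_minutes,
    sleep_minutes,calories. Missing cells become NaN; gaps in the calendar
    become missing days. Malformed rows are reported with line numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"child_id": str})
    if "child_id" not in frame.columns or "date" not in frame.columns:
        raise ValidationError(f"{path}: header must contain child_id and date")
    variables = [c for c in frame.columns if c in WEARABLE_VARIABLES]
    if not variables:
        raise ValidationError(
            f"{path}: no known wearable variable columns (expected some of {WEARABLE_VARIABLES})"
        )
    errors: list[str] = []
    dates = []
    for i, raw in enumerate(frame["date"]):
        dates.append(_parse_date(raw, i + 2, errors))
    frame = frame.assign(_date=dates)
    for var in variables:
        bad = frame.index[pd.to_numeric(frame[var], errors="coerce") < 0]
        errors.extend(f"line {i + 2}: negative {var}" for i in bad)
    dup = frame.duplicated(["child_id", "date"])
    errors.extend(
        f"line {i + 2}: duplicate (child_id={frame.at[i, 'child_id']}, date={frame.at[i, 'date']})"
        for i in frame.index[dup]
    )
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))

    out: list[DailyTimeSeries] = []
    for child_id, grp in frame.groupby("child_id", sort=True):
        grp = grp.sort_values("_date")
        start, end = grp["_date"].iloc[0], grp["_date"].iloc[-1]
        n = (end - start).days + 1
        by_date = {d: i for i, d in enumerate(grp["_date"])}
        for var in variables:
            values = np.full(n, np.nan)
            col = pd.to_numeric(grp[var], errors="coerce").to_numpy()
            for d, row_i in by_date.items():
                values[(d - start).days] = col[row_i]
            out.append(DailyTimeSeries(str(child_id), var, start, values))
    return out


def write_wearable_csv(path: str | Path, series: Sequence[DailyTimeSeries]) -> None:
    frames = {}
    for ts in series:
        for date, value in zip(ts.dates, ts.values):
            key = (ts.child_id, date.isoformat())
            frames.setdefault(key, {})[ts.variable_id] = value
    variables = sorted({ts.variable_id for ts in series},
                       key=WEARABLE_VARIABLES.index)
    lines = ["child_id,date," + ",".join(variables)]
    for (child_id, date), values in sorted(frames.items()):
        cells = []
        for var in variables:
            v = values.get(var)
            cells.append("" if v is None or not np.isfinite(v) else f"{v:.6g}")
        lines.append(f"{child_id},{date}," + ",".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# anthropometrics and profiles

def read_anthropometrics_csv(path: str | Path) -> list[AnthropometricRecord]:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"child_id": str})
    required = {"child_id", "date", "weight_kg", "height_m"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    errors: list[str] = []
    records = []
    for i, row in frame.iterrows():
        date = _parse_date(row["date"], i + 2, errors)
        if date is None:
            continue
        try:
            records.append(
                AnthropometricRecord(
                    child_id=str(row["child_id"]),
                    date=date,
                    weight_kg=float(row["weight_kg"]),
                    height_m=float(row["height_m"]),
                    waist_cm=_opt_float(row.get("waist_cm")),
                    hip_cm=_opt_float(row.get("hip_cm")),
                    fat_mass_pct=_opt_float(row.get("fat_mass_pct")),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return records


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def write_anthropometrics_csv(path: str | Path, records: Sequence[AnthropometricRecord]) -> None:
    lines = ["child_id,date,weight_kg,height_m,waist_cm,hip_cm,fat_mass_pct"]
    for r in records:
        opt = [r.waist_cm, r.hip_cm, r.fat_mass_pct]
        cells = ["" if v is None else f"{v:g}" for v in opt]
        lines.append(f"{r.child_id},{r.date.isoformat()},{r.weight_kg:g},{r.height_m:g}," + ",".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_profiles_csv(path: str | Path, profiles: Sequence[ChildProfile]) -> None:
    lines = ["child_id,sex,birth_date,pilot_site"]
    for p in profiles:
        lines.append(f"{p.child_id},{p.sex.value},{p.birth_date.isoformat()},{p.pilot_site or ''}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_profiles_csv(path: str | Path) -> list[ChildProfile]:
    frame = pd.read_csv(path, dtype={"child_id": str})
    return [
        ChildProfile(
            str(r.child_id), Sex(r.sex), dt.date.fromisoformat(r.birth_date),
            None if pd.isna(r.pilot_site) else str(r.pilot_site),
        )
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# questionnaires, plans, outcomes, flag histories

def questionnaire_to_dict(q: QuestionnaireResponse) -> dict:
    return {
        "child_id": q.child_id,
        "week_id": q.week_id,
        "instrument": q.instrument.value,
        "items": [[i, v] for i, v in q.items],
    }


def questionnaire_from_dict(d: Mapping) -> QuestionnaireResponse:
    return QuestionnaireResponse(
        child_id=str(d["child_id"]),
        week_id=str(d["week_id"]),
        instrument=Instrument(d["instrument"]),
        items=tuple((str(i), v) for i, v in d["items"]),
    )


def write_questionnaires_json(path: str | Path, qs: Sequence[QuestionnaireResponse]) -> None:
    write_json(path, [questionnaire_to_dict(q) for q in qs])


def read_questionnaires_json(path: str | Path) -> list[QuestionnaireResponse]:
    data = json.loads(Path(path).read_text())
    return [questionnaire_from_dict(d) for d in data]


def plan_to_dict(plan: CoachingPlan) -> dict:
    return {
        "child_id": plan.child_id,
        "week_id": plan.week_id,
        "missions": [m.model_dump(mode="json") for m in plan.missions],
        "rationale": dict(plan.rationale),
    }


def plan_from_dict(d: Mapping) -> CoachingPlan:
    return CoachingPlan(
        child_id=str(d["child_id"]),
        week_id=str(d["week_id"]),
        missions=tuple(Mission.model_validate(m) for m in d["missions"]),
        rationale=dict(d.get("rationale", {})),
    )


def write_plans_json(path: str | Path, plans: Sequence[CoachingPlan]) -> None:
    write_json(path, [plan_to_dict(p) for p in plans])


def read_plans_json(path: str | Path) -> list[CoachingPlan]:
    return [plan_from_dict(d) for d in json.loads(Path(path).read_text())]


def outcome_to_dict(o: MissionOutcome) -> dict:
    return {
        "mission_id": o.mission_id,
        "child_id": o.child_id,
        "week_id": o.week_id,
        "status": o.status.value,
        "validated_by": o.validated_by.value,
    }


def outcome_from_dict(d: Mapping) -> MissionOutcome:
    return MissionOutcome(
        mission_id=int(d["mission_id"]),
        child_id=str(d["child_id"]),
        week_id=str(d["week_id"]),
        status=OutcomeStatus(d["status"]),
        validated_by=Validator(d["validated_by"]),
    )


def write_flag_histories_csv(path: str | Path, histories: Mapping[str, Mapping[str, FlagHistory]]) -> None:
    """child -> behaviour -> FlagHistory, as child_id,behaviour_id,week,flag rows."""
    lines = ["child_id,behaviour_id,week,flag"]
    for child_id in sorted(histories):
        for behaviour_id in sorted(histories[child_id]):
            h = histories[child_id][behaviour_id]
            for week, flag in zip(h.weeks, h.flags):
                lines.append(f"{child_id},{behaviour_id},{week},{flag}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_flag_histories_csv(path: str | Path) -> dict[str, dict[str, FlagHistory]]:
    frame = pd.read_csv(path, dtype=str)
    out: dict[str, dict[str, FlagHistory]] = {}
    for r in frame.itertuples():
        hist = out.setdefault(str(r.child_id), {}).setdefault(
            str(r.behaviour_id), FlagHistory(str(r.behaviour_id))
        )
        hist.append(str(r.week), FlagStatus[str(r.flag)])
    return out


# ---------------------------------------------------------------------------
# cohort report

@dataclass
class CohortReport:
    """Cohort-level summary: status prevalences, flag distributions,
    mission completion and mean monitored values."""

    n_children: int
    status_counts: dict[str, int]
    status_prevalence_pct: dict[str, float]  # sums to 100 over the 5 statuses
    flag_distribution_by_week: dict[str, dict[str, int]]
    missions_assigned: int
    missions_completed: int
    mean_values_by_week: dict[str, dict[str, float]]

    @property
    def completion_rate_pct(self) -> float:
        if self.missions_assigned == 0:
            return 0.0
        return 100.0 * self.missions_completed / self.missions_assigned

    def to_dict(self) -> dict:
        return {
            "n_children": self.n_children,
            "status_counts": self.status_counts,
            "status_prevalence_pct": self.status_prevalence_pct,
            "flag_distribution_by_week": self.flag_distribution_by_week,
            "missions_assigned": self.missions_assigned,
            "missions_completed": self.missions_completed,
            "completion_rate_pct": self.completion_rate_pct,
            "mean_values_by_week": self.mean_values_by_week,
        }


def cohort_report(
    statuses: Mapping[str, NutritionalStatus | str],
    flags_by_week: Mapping[str, Mapping[str, Mapping[str, FlagStatus]]] | None = None,
    outcomes: Sequence[MissionOutcome] = (),
    weekly_values: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
) -> CohortReport:
    """Exact counts and ratios over a classified cohort.

    ``statuses``: child -> nutritional status. ``flags_by_week``:
    week -> child -> behaviour -> flag. ``weekly_values``:
    week -> child -> variable -> value.
    """
    if not statuses:
        raise ValidationError("empty cohort")
    counts = {s.value: 0 for s in STATUS_ORDER}
    for status in statuses.values():
        key = status.value if isinstance(status, NutritionalStatus) else str(status)
        if key not in counts:
            raise ValidationError(f"unknown nutritional status {key!r}")
        counts[key] += 1
    n = len(statuses)
    prevalence = {s: 100.0 * c / n for s, c in counts.items()}

    flag_dist: dict[str, dict[str, int]] = {}
    for week, by_child in (flags_by_week or {}).items():
        dist = {"green": 0, "yellow": 0, "red": 0}
        for flags in by_child.values():
            for flag in flags.values():
                dist[str(flag)] += 1
        flag_dist[week] = dist

    assigned = len(outcomes)
    completed = sum(1 for o in outcomes if o.status is OutcomeStatus.completed)

    means: dict[str, dict[str, float]] = {}
    for week, by_child in (weekly_values or {}).items():
        frame = pd.DataFrame.from_dict(by_child, orient="index")
        means[week] = {c: float(frame[c].mean()) for c in frame.columns}

    return CohortReport(
        n_children=n,
        status_counts=counts,
        status_prevalence_pct=prevalence,
        flag_distribution_by_week=flag_dist,
        missions_assigned=assigned,
        missions_completed=completed,
        mean_values_by_week=means,
    )
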