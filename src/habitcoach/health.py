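"""Anthropometric classification, questionnaire scoring and three-level risk
stratification.

The growth side uses the LMS method: a measurement ``x`` (here BMI) is mapped
to a z-score against an age- and sex-specific reference described by a
skewness parameter ``L``, a median ``M`` and a coefficient of variation ``S``:

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = ln(x / M) / S                     for L == 0

Nutritional status follows the school-age convention of five z-score bands
(severe thinness < -3, thinness < -2, normal <= +1, overweight <= +2,
obesity > +2), with each boundary belonging to the less severe band.

The behavioural side stratifies every monitored variable (food-group weekly
frequencies, PAQ-C composite, wearable summaries) into a green/yellow/red
flag using per-variable cut-offs that live in configuration, since they come
from programme-specific baseline evidence rather than from a universal table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from .types import FlagStatus, NutritionalStatus, Sex

logger = logging.getLogger(__name__)

# |L| below this is treated as the L -> 0 log-normal limit; keeps the
# transform numerically continuous (the raw closed form loses ~|L| digits).
_L_LOG_SWITCH = 1e-5

#: z-score boundaries of the five nutritional-status bands.
Z_CUTOFFS = (-3.0, -2.0, 1.0, 2.0)

#: |z| beyond this is logged as a suspect record (device/entry error guard).
SUSPECT_Z = 5.0


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index in kg/m²."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


@dataclass(frozen=True)
class LMSRow:
    """One growth-reference row: skewness L, median M, coefficient of variation S."""

    sex: Sex
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0 or self.S <= 0:
            raise ValueError(f"M and S must be positive, got M={self.M}, S={self.S}")


def lms_zscore(x: float, row: LMSRow) -> float:
    """z-score of a measurement against an LMS reference row.

    Strictly increasing in ``x``; exactly 0 at the median ``x = M``.
    """
    if x <= 0:
        raise ValueError(f"measurement must be positive, got {x}")
    ratio = x / row.M
    if abs(row.L) < _L_LOG_SWITCH:
        z = math.log(ratio) / row.S
    else:
        z = (ratio**row.L - 1.0) / (row.L * row.S)
    if abs(z) > SUSPECT_Z:
        logger.warning(
            "suspect measurement: |z|=%.2f beyond %.1f (x=%g, age=%s months, sex=%s)",
            z, SUSPECT_Z, x, row.age_months, row.sex.value,
        )
    return z


def lms_inverse(z: float, row: LMSRow) -> float:
    """Measurement value at a given z-score (inverse of :func:`lms_zscore`)."""
    if abs(row.L) < _L_LOG_SWITCH:
        return row.M * math.exp(row.S * z)
    base = 1.0 + row.L * row.S * z
    if base <= 0:
        raise ValueError(
            f"z={z} outside the invertible range of the reference row (L={row.L}, S={row.S})"
        )
    return row.M * base ** (1.0 / row.L)


class LMSTable:
    """Growth-reference table indexed by (sex, age in months).

    Ages between tabulated months are linearly interpolated on (L, M, S).
    """

    def __init__(self, rows: Sequence[LMSRow]):
        if not rows:
            raise ValueError("empty LMS table")
        self._by_sex: dict[Sex, pd.DataFrame] = {}
        frame = pd.DataFrame(
            [(r.sex, r.age_months, r.L, r.M, r.S) for r in rows],
            columns=["sex", "age_months", "L", "M", "S"],
        )
        if frame.duplicated(["sex", "age_months"]).any():
            dup = frame[frame.duplicated(["sex", "age_months"])].iloc[0]
            raise ValueError(
                f"duplicate LMS row for sex={dup['sex']}, age_months={dup['age_months']}"
            )
        for sex, grp in frame.groupby("sex"):
            self._by_sex[Sex(sex)] = grp.sort_values("age_months").set_index("age_months")

    @classmethod
    def from_csv(cls, path) -> "LMSTable":
        """Read a reference CSV with columns sex,age_months,L,M,S."""
        frame = pd.read_csv(path, comment="#")
        required = {"sex", "age_months", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"LMS CSV {path} missing columns: {sorted(missing)}")
        rows = [
            LMSRow(Sex(r.sex), float(r.age_months), float(r.L), float(r.M), float(r.S))
            for r in frame.itertuples()
        ]
        return cls(rows)

    def age_range(self, sex: Sex) -> tuple[float, float]:
        idx = self._by_sex[sex].index
        return float(idx.min()), float(idx.max())

    def lookup(self, sex: Sex, age_months: float) -> LMSRow:
        try:
            table = self._by_sex[sex]
        except KeyError:
            raise ValueError(f"no LMS rows for sex={sex.value}") from None
        lo, hi = float(table.index.min()), float(table.index.max())
        if not (lo <= age_months <= hi):
            raise ValueError(
                f"age {age_months} months outside reference range [{lo}, {hi}]"
            )
        if age_months in table.index:
            r = table.loc[age_months]
            return LMSRow(sex, age_months, float(r.L), float(r.M), float(r.S))
        below = table.index[table.index <= age_months].max()
        above = table.index[table.index >= age_months].min()
        w = (age_months - below) / (above - below)
        lo_r, hi_r = table.loc[below], table.loc[above]
        return LMSRow(
            sex,
            age_months,
            float((1 - w) * lo_r.L + w * hi_r.L),
            float((1 - w) * lo_r.M + w * hi_r.M),
            float((1 - w) * lo_r.S + w * hi_r.S),
        )

    def zscore(self, x: float, sex: Sex, age_months: float) -> float:
        return lms_zscore(x, self.lookup(sex, age_months))


def classify_nutritional_status(z: float) -> NutritionalStatus:
    """Five-level nutritional status from a BMI-for-age z-score.

    Bands: z < -3 severe thinness; -3 <= z < -2 thinness; -2 <= z <= +1
    normal; +1 < z <= +2 overweight; z > +2 obesity.
    """
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    if z < Z_CUTOFFS[0]:
        return NutritionalStatus.severe_thinness
    if z < Z_CUTOFFS[1]:
        return NutritionalStatus.thinness
    if z <= Z_CUTOFFS[2]:
        return NutritionalStatus.normal
    if z <= Z_CUTOFFS[3]:
        return NutritionalStatus.overweight
    return NutritionalStatus.obesity


def categorize_by_cutoffs(value: float, cutoffs: Sequence[float], labels: Sequence[str]) -> str:
    """Generic ordinal classifier: label of the half-open interval containing value.

    Intervals are [low, high) except the last, which is unbounded above. Used
    for fat-mass % and waist-based (abdominal obesity) categorisation against
    user-supplied reference cut-offs.
    """
    if len(labels) != len(cutoffs) + 1:
        raise ValueError(
            f"need len(labels) == len(cutoffs) + 1, got {len(labels)} labels, {len(cutoffs)} cutoffs"
        )
    if any(a >= b for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"cutoffs must be strictly increasing, got {list(cutoffs)}")
    for cut, label in zip(cutoffs, labels):
        if value < cut:
            return label
    return labels[-1]


def score_paqc(items: Sequence[int], n_items: int = 9) -> float:
    """PAQ-C composite: unweighted mean of item scores, each on 1-5."""
    if len(items) != n_items:
        raise ValueError(f"expected {n_items} PAQ-C items, got {len(items)}")
    for v in items:
        if v not in (1, 2, 3, 4, 5):
            raise ValueError(f"PAQ-C item values must be integers 1-5, got {v!r}")
    return sum(items) / len(items)


#: Default food-frequency category -> weekly frequency mapping. Ranged
#: categories use the midpoint convention ("2-3/week" -> 2.5).
DEFAULT_FFQ_MAPPING: dict[str, float] = {
    "never": 0.0,
    "<1/week": 0.5,
    "1/week": 1.0,
    "2-3/week": 2.5,
    "4-6/week": 5.0,
    "daily": 7.0,
    "2+/day": 14.0,
}


def map_ffq_frequency(category: str, mapping: Mapping[str, float] | None = None) -> float:
    """Weekly consumption frequency for a food-frequency category string."""
    mapping = DEFAULT_FFQ_MAPPING if mapping is None else mapping
    try:
        freq = float(mapping[category])
    except KeyError:
        raise ValueError(
            f"unknown FFQ category {category!r}; known: {sorted(mapping)}"
        ) from None
    if freq < 0:
        raise ValueError(f"mapped frequency must be non-negative, got {freq}")
    return freq


class StratificationRule(BaseModel):
    """Three-level risk stratification of one variable.

    ``higher_is_worse`` needs green_yellow_cutoff < yellow_red_cutoff;
    ``lower_is_worse`` the reverse. Boundary values belong to the less
    severe band.
    """

    variable_id: str
    direction: str  # "higher_is_worse" | "lower_is_worse"
    green_yellow_cutoff: float
    yellow_red_cutoff: float
    units: str = ""

    @field_validator("direction")
    @classmethod
    def _known_direction(cls, v: str) -> str:
        if v not in ("higher_is_worse", "lower_is_worse"):
            raise ValueError(f"unknown direction {v!r}")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "StratificationRule":
        if self.direction == "higher_is_worse":
            if not self.green_yellow_cutoff < self.yellow_red_cutoff:
                raise ValueError(
                    f"{self.variable_id}: higher_is_worse needs green_yellow < yellow_red, "
                    f"got {self.green_yellow_cutoff} >= {self.yellow_red_cutoff}"
                )
        else:
            if not self.green_yellow_cutoff > self.yellow_red_cutoff:
                raise ValueError(
                    f"{self.variable_id}: lower_is_worse needs green_yellow > yellow_red, "
                    f"got {self.green_yellow_cutoff} <= {self.yellow_red_cutoff}"
                )
        return self

    def mirrored(self) -> "StratificationRule":
        """The same rule on the negated axis (direction reversed, cut-offs negated)."""
        return StratificationRule(
            variable_id=self.variable_id,
            direction=(
                "lower_is_worse" if self.direction == "higher_is_worse" else "higher_is_worse"
            ),
            green_yellow_cutoff=-self.green_yellow_cutoff,
            yellow_red_cutoff=-self.yellow_red_cutoff,
            units=self.units,
        )


def stratify_variable(value: float, rule: StratificationRule) -> FlagStatus:
    """Green/yellow/red flag of a value under a stratification rule."""
    if rule.direction == "higher_is_worse":
        if value <= rule.green_yellow_cutoff:
            return FlagStatus.green
        if value <= rule.yellow_red_cutoff:
            return FlagStatus.yellow
        return FlagStatus.red
    if value >= rule.green_yellow_cutoff:
        return FlagStatus.green
    if value >= rule.yellow_red_cutoff:
        return FlagStatus.yellow
    return FlagStatus.red


def adjust_pa_target(
    baseline: float, week_index: int, delta: float, target_level: float
) -> float:
    """Weekly physical-activity goal: dynamic percentage increase over the
    individual baseline, capped at the target level.

    Week ``w`` goal is ``min(baseline * (1 + delta)**w, target_level)``;
    non-decreasing in ``w`` and equal to the target for large ``w``.
    """
    if baseline < 0:
        raise ValueError(f"baseline must be non-negative, got {baseline}")
    if week_index < 0:
        raise ValueError(f"week_index must be non-negative, got {week_index}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if target_level < baseline:
        raise ValueError(
            f"target_level {target_level} below baseline {baseline} for a higher-is-better goal"
        )
    return min(baseline * (1.0 + delta) ** week_index, target_level)
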