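"""Interval-binning rubrics for the twelve PHISS parameters.

Each parameter of the Public Health Impact Severity Scale maps a raw
indicator value (a count, a rate, a percentage, or an ordinal level) onto an
integer severity score through an ordered set of bins.  The twelve shipped
rubrics are grounded in the Sphere Project minimum standards and in the
CRED/EM-DAT disaster-registry entry criteria (>=10 killed, >=100 affected);
their maximum scores sum to exactly 100, which is the ceiling of the
cumulative scale.

The bin engine is generic: a :class:`RubricTable` is an ordered, gap-free,
overlap-free partition of the admissible domain, and :func:`bin_score` looks
a value up by bisection.  Rubrics serialize to YAML/JSON so users can audit
or override the shipped tables.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MeasureKind",
    "Direction",
    "SphereCategory",
    "ScoreBin",
    "OrdinalLevel",
    "RubricTable",
    "RubricValidationReport",
    "RubricError",
    "InadmissibleValueError",
    "PARAMETER_IDS",
    "bin_score",
    "validate_rubric",
    "builtin_rubrics",
    "load_rubrics",
    "dump_rubrics",
]

INF = math.inf

#: Canonical parameter identifiers, in presentation order P1..P12.
PARAMETER_IDS: tuple[str, ...] = (
    "excess_deaths",
    "under5_excess_deaths",
    "communicable_cases",
    "injury_cases",
    "healthcare_level",
    "malnourished_children",
    "displaced_persons",
    "inadequate_space_persons",
    "water_quantity_lpd",
    "water_quality_pct",
    "sanitation_level",
    "gbv_level",
)


class RubricError(ValueError):
    """A rubric is structurally invalid or cannot score a value."""


class InadmissibleValueError(RubricError):
    """A raw value lies outside the admissible domain of its parameter."""


class MeasureKind(str, Enum):
    COUNT = "count"
    RATE_PER_PERSON_DAY = "rate-per-person-day"
    PERCENTAGE = "percentage"
    ORDINAL = "ordinal"


class Direction(str, Enum):
    #: severity rises with the raw value (all parameters except water quantity)
    INCREASING = "severity-increasing"
    #: severity falls with the raw value (water quantity only)
    DECREASING = "severity-decreasing"


class SphereCategory(str, Enum):
    HEALTH = "health"
    FOOD_NUTRITION = "food-nutrition"
    SHELTER = "shelter"
    WATER_SANITATION = "water-sanitation"


class ScoreBin(BaseModel):
    """One row of a scoring table: an interval of raw values and its score.

    Intervals are half-open ``[lower, upper)`` by default; the inclusivity
    flags accommodate the two printed exceptions (the "12.5-15 l/p/d" water
    bin closes at 15, and ">15" opens at 15) and single-level ordinal bins
    (``lower == upper``, both inclusive).
    """

    model_config = ConfigDict(frozen=True)

    lower: float
    upper: float
    score: int = Field(ge=0, le=10)
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    @model_validator(mode="after")
    def _check_interval(self) -> "ScoreBin":
        if self.lower > self.upper:
            raise ValueError(f"bin lower {self.lower} exceeds upper {self.upper}")
        if self.lower == self.upper and not (self.lower_inclusive and self.upper_inclusive):
            raise ValueError("a degenerate (single-point) bin must be closed on both sides")
        return self

    def contains(self, value: float) -> bool:
        above = value >= self.lower if self.lower_inclusive else value > self.lower
        below = value <= self.upper if self.upper_inclusive else value < self.upper
        return above and below


class OrdinalLevel(BaseModel):
    """A named level of an ordinal parameter (healthcare, sanitation, GBV)."""

    model_config = ConfigDict(frozen=True)

    parameter_id: str
    level_code: int = Field(ge=0)
    description: str


class RubricTable(BaseModel):
    """The machine form of one PHISS scoring table.

    ``bins`` are ordered by raw value (ascending ``lower``); for the
    severity-decreasing water-quantity rubric this means scores run downward
    along the list.  ``levels`` is populated for ordinal parameters only and
    documents what each level code means.
    """

    model_config = ConfigDict(frozen=True)

    parameter_id: str
    name: str
    measure_kind: MeasureKind
    direction: Direction = Direction.INCREASING
    category: SphereCategory
    bins: tuple[ScoreBin, ...]
    max_score: int = Field(ge=0, le=10)
    levels: tuple[OrdinalLevel, ...] = ()

    @model_validator(mode="after")
    def _check_sorted(self) -> "RubricTable":
        lowers = [b.lower for b in self.bins]
        if lowers != sorted(lowers):
            raise ValueError(f"{self.parameter_id}: bins must be ordered by lower bound")
        if not self.bins:
            raise ValueError(f"{self.parameter_id}: rubric has no bins")
        return self

    # -- admissibility -----------------------------------------------------

    def check_admissible(self, value: Union[int, float]) -> float:
        """Validate a raw value for this rubric's measure kind.

        Returns the value as a float; raises :class:`InadmissibleValueError`
        naming the parameter otherwise.
        """
        pid = self.parameter_id
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise InadmissibleValueError(f"{pid}: value {value!r} is not numeric")
        if math.isnan(value) or math.isinf(value):
            raise InadmissibleValueError(f"{pid}: value {value!r} is not finite")
        if value < 0:
            raise InadmissibleValueError(f"{pid}: value {value} is negative")
        if self.measure_kind is MeasureKind.COUNT and value != int(value):
            raise InadmissibleValueError(f"{pid}: count {value} is not an integer")
        if self.measure_kind is MeasureKind.PERCENTAGE and value > 100:
            raise InadmissibleValueError(f"{pid}: percentage {value} exceeds 100")
        if self.measure_kind is MeasureKind.ORDINAL:
            codes = {lvl.level_code for lvl in self.levels}
            if value != int(value) or int(value) not in codes:
                raise InadmissibleValueError(
                    f"{pid}: undefined ordinal level {value!r} (defined: {sorted(codes)})"
                )
        return float(value)


class RubricValidationReport(BaseModel):
    """Findings from a structural audit of one rubric (empty = pass)."""

    parameter_id: str
    findings: list[str] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


# ---------------------------------------------------------------------------
# operations


def bin_score(table: RubricTable, value: Union[int, float]) -> int:
    """Return the severity score of the unique bin containing ``value``.

    Lookup is by bisection on the bins' lower bounds, with a one-step
    adjustment for the open/closed boundary conventions.
    """
    v = table.check_admissible(value)
    lowers = [b.lower for b in table.bins]
    idx = min(bisect_right(lowers, v) - 1, len(table.bins) - 1)
    for j in (idx, idx - 1, idx + 1):
        if 0 <= j < len(table.bins) and table.bins[j].contains(v):
            return table.bins[j].score
    raise RubricError(f"{table.parameter_id}: no bin covers admissible value {value}")


def validate_rubric(table: RubricTable) -> RubricValidationReport:
    """Audit a rubric for gaps, overlaps, monotonicity and max-score faults.

    Returns findings rather than raising, so user-supplied override rubrics
    can be reported on wholesale.
    """
    findings: list[str] = []
    bins = table.bins

    if bins[0].lower != 0 or not bins[0].lower_inclusive:
        findings.append(f"domain floor not covered: first bin starts at {bins[0].lower}")
    terminal = bins[-1]
    if table.measure_kind is MeasureKind.PERCENTAGE:
        if not terminal.contains(100.0):
            findings.append("domain ceiling not covered: 100% falls in no bin")
    elif table.measure_kind is MeasureKind.ORDINAL:
        pass  # coverage of ordinal codes checked against declared levels below
    elif terminal.upper != INF:
        findings.append(f"domain ceiling not covered: last bin ends at {terminal.upper}")

    for prev, nxt in zip(bins, bins[1:]):
        if prev.upper > nxt.lower or (
            prev.upper == nxt.lower and prev.upper_inclusive and nxt.lower_inclusive
        ):
            findings.append(f"overlap between bins scoring {prev.score} and {nxt.score}")
        elif table.measure_kind is not MeasureKind.ORDINAL and (
            prev.upper < nxt.lower
            or (
                prev.upper == nxt.lower
                and not prev.upper_inclusive
                and not nxt.lower_inclusive
            )
        ):
            # ordinal codes are integer points; adjacency is checked below
            findings.append(f"gap between bins scoring {prev.score} and {nxt.score}")

    if table.measure_kind is MeasureKind.ORDINAL:
        covered = sorted(b.lower for b in bins)
        declared = sorted(lvl.level_code for lvl in table.levels)
        if covered != declared:
            findings.append(f"ordinal bins {covered} do not match declared levels {declared}")

    scores = [b.score for b in bins]
    if table.direction is Direction.INCREASING:
        if any(a > b for a, b in zip(scores, scores[1:])):
            findings.append("scores are not non-decreasing along the raw-value axis")
    else:
        if any(a < b for a, b in zip(scores, scores[1:])):
            findings.append("scores are not non-increasing along the raw-value axis")

    if max(scores) != table.max_score:
        findings.append(
            f"declared max_score {table.max_score} != largest bin score {max(scores)}"
        )

    return RubricValidationReport(parameter_id=table.parameter_id, findings=findings)


# ---------------------------------------------------------------------------
# the twelve shipped rubrics


def _count_bins(edges: Sequence[int]) -> tuple[ScoreBin, ...]:
    """Half-open count bins [e_k, e_{k+1}) scoring 0,1,2,... with a +inf tail."""
    bounds = [0, *edges, INF]
    return tuple(
        ScoreBin(lower=lo, upper=hi, score=k)
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    )


def _ordinal_bins(levels: Iterable[OrdinalLevel]) -> tuple[ScoreBin, ...]:
    return tuple(
        ScoreBin(
            lower=lvl.level_code,
            upper=lvl.level_code,
            score=lvl.level_code,
            upper_inclusive=True,
        )
        for lvl in levels
    )


# Count-rubric bin edges.  Floors follow the CRED/EM-DAT registry criteria:
# 10 for the two death counts (>=10 killed), 20 for the five affected-person
# counts (so five floors of 20 jointly meet the >=100-affected criterion).
_DEATH_EDGES = [10, 100, 1_000, 5_000, 10_000, 20_000, 50_000, 100_000, 200_000, 300_000]
_U5_EDGES = [10, 100, 1_000, 5_000, 10_000, 20_000, 30_000, 40_000, 50_000, 60_000]
_AFFECTED_EDGES = [20, 100, 1_000, 5_000, 10_000, 20_000, 30_000, 40_000, 50_000, 60_000]
_INJURY_EDGES = [20, 100, 1_000, 5_000, 10_000, 20_000, 50_000, 100_000, 200_000, 300_000]
_DISPLACED_EDGES = [20, 100, 1_000, 10_000, 50_000, 100_000, 200_000, 500_000, 1_000_000]
_SPACE_EDGES = [20, 100, 1_000, 5_000, 10_000, 20_000, 50_000, 100_000, 200_000]

HEALTHCARE_LEVELS = tuple(
    OrdinalLevel(parameter_id="healthcare_level", level_code=c, description=d)
    for c, d in [
        (0, "All levels of health care system are intact"),
        (1, "Disrupted fourth level of health care; intact third, second and first levels"),
        (2, "Disrupted fourth and third levels of health care; intact second and first levels"),
        (3, "Disrupted second, third and fourth levels of health care; intact first level"),
        (4, "All levels of health care disrupted"),
    ]
)

SANITATION_LEVELS = tuple(
    OrdinalLevel(parameter_id="sanitation_level", level_code=c, description=d)
    for c, d in [
        (0, "Intact well developed sanitary system for disposal of excreta"),
        (1, "Minor disruption of a well developed sanitary system for disposal of excreta"),
        (2, "Two or more toilets (or latrines) per 20 people, or two or more family latrines "
            "per 4 families, or two or more trench latrines per 100 people"),
        (3, "One toilet (or latrine) per 20 people, or one family latrine per 4 families, "
            "or one trench latrine per 100 people"),
        (4, "Less than one toilet (or latrine) per 20 people, or one family latrine per "
            "4 families, or one trench latrine per 100 people"),
        (5, "Complete absence of any system for disposal of excreta"),
    ]
)

GBV_LEVELS = tuple(
    OrdinalLevel(parameter_id="gbv_level", level_code=c, description=d)
    for c, d in [
        (0, "None"),
        (1, "Isolated single events (not daily)"),
        (2, "Average occurrences approximately one daily"),
        (3, "Average occurrences approximately multiple daily"),
        (4, "Systematic gender-based violence"),
    ]
)

# Water quantity: severity falls as liters/person/day rise.  Printed bands
# have one-decimal label gaps ("10-12.4", "7.5-9.9"); they are encoded as
# contiguous half-open real intervals so the domain is gap-free.  The
# "12.5-15" band closes at 15 and ">15" opens there.
_WATER_QTY_BINS = (
    ScoreBin(lower=0.0, upper=2.5, score=9),
    ScoreBin(lower=2.5, upper=3.5, score=8),
    ScoreBin(lower=3.5, upper=4.5, score=7),
    ScoreBin(lower=4.5, upper=5.5, score=6),
    ScoreBin(lower=5.5, upper=6.5, score=5),
    ScoreBin(lower=6.5, upper=7.5, score=4),
    ScoreBin(lower=7.5, upper=10.0, score=3),
    ScoreBin(lower=10.0, upper=12.5, score=2),
    ScoreBin(lower=12.5, upper=15.0, score=1, upper_inclusive=True),
    ScoreBin(lower=15.0, upper=INF, score=0, lower_inclusive=False),
)

# Water quality: 0 only for exactly 0% polluted samples; decile bands above;
# the top band is encoded as >=90% so that exactly 90% is covered
# (severity-conservative reading of the printed ">90%").
_WATER_QUAL_BINS = (
    ScoreBin(lower=0.0, upper=0.0, score=0, upper_inclusive=True),
    ScoreBin(lower=0.0, upper=10.0, score=1, lower_inclusive=False),
    *(
        ScoreBin(lower=10.0 * k, upper=10.0 * (k + 1), score=k + 1)
        for k in range(1, 9)
    ),
    ScoreBin(lower=90.0, upper=100.0, score=10, upper_inclusive=True),
)


def builtin_rubrics() -> list[RubricTable]:
    """The twelve shipped PHISS rubrics, in presentation order P1-P12.

    Maximum scores are 10, 10, 10, 10, 4, 10, 9, 9, 9, 10, 5, 4 and sum to
    100, the ceiling of the cumulative scale.
    """
    C = SphereCategory
    return [
        RubricTable(
            parameter_id="excess_deaths",
            name="Total number of excess deaths",
            measure_kind=MeasureKind.COUNT,
            category=C.HEALTH,
            bins=_count_bins(_DEATH_EDGES),
            max_score=10,
        ),
        RubricTable(
            parameter_id="under5_excess_deaths",
            name="Number of under-5 excess deaths",
            measure_kind=MeasureKind.COUNT,
            category=C.HEALTH,
            bins=_count_bins(_U5_EDGES),
            max_score=10,
        ),
        RubricTable(
            parameter_id="communicable_cases",
            name="Number of cases with acute communicable diseases",
            measure_kind=MeasureKind.COUNT,
            category=C.HEALTH,
            bins=_count_bins(_AFFECTED_EDGES),
            max_score=10,
        ),
        RubricTable(
            parameter_id="injury_cases",
            name="Number of cases with traumatic/chemical/radiological injuries",
            measure_kind=MeasureKind.COUNT,
            category=C.HEALTH,
            bins=_count_bins(_INJURY_EDGES),
            max_score=10,
        ),
        RubricTable(
            parameter_id="healthcare_level",
            name="Levels of health care services",
            measure_kind=MeasureKind.ORDINAL,
            category=C.HEALTH,
            bins=_ordinal_bins(HEALTHCARE_LEVELS),
            max_score=4,
            levels=HEALTHCARE_LEVELS,
        ),
        RubricTable(
            parameter_id="malnourished_children",
            name="Number of young children (6-59 months) with acute malnutrition",
            measure_kind=MeasureKind.COUNT,
            category=C.FOOD_NUTRITION,
            bins=_count_bins(_AFFECTED_EDGES),
            max_score=10,
        ),
        RubricTable(
            parameter_id="displaced_persons",
            name="Number of displaced persons (IDPs and refugees)",
            measure_kind=MeasureKind.COUNT,
            category=C.SHELTER,
            bins=_count_bins(_DISPLACED_EDGES),
            max_score=9,
        ),
        RubricTable(
            parameter_id="inadequate_space_persons",
            name="Number of persons with inadequate living space",
            measure_kind=MeasureKind.COUNT,
            category=C.SHELTER,
            bins=_count_bins(_SPACE_EDGES),
            max_score=9,
        ),
        RubricTable(
            parameter_id="water_quantity_lpd",
            name="Water quantity (liters/person/day)",
            measure_kind=MeasureKind.RATE_PER_PERSON_DAY,
            direction=Direction.DECREASING,
            category=C.WATER_SANITATION,
            bins=_WATER_QTY_BINS,
            max_score=9,
        ),
        RubricTable(
            parameter_id="water_quality_pct",
            name="Percentage of water samples with more than 10 fecal coliforms/100 ml",
            measure_kind=MeasureKind.PERCENTAGE,
            category=C.WATER_SANITATION,
            bins=_WATER_QUAL_BINS,
            max_score=10,
        ),
        RubricTable(
            parameter_id="sanitation_level",
            name="Levels of sanitation facilities",
            measure_kind=MeasureKind.ORDINAL,
            category=C.WATER_SANITATION,
            bins=_ordinal_bins(SANITATION_LEVELS),
            max_score=5,
            levels=SANITATION_LEVELS,
        ),
        RubricTable(
            parameter_id="gbv_level",
            name="Gender-based violence",
            measure_kind=MeasureKind.ORDINAL,
            category=C.HEALTH,
            bins=_ordinal_bins(GBV_LEVELS),
            max_score=4,
            levels=GBV_LEVELS,
        ),
    ]


# ---------------------------------------------------------------------------
# serialization (audit / override files)


def _table_to_plain(t: RubricTable) -> dict:
    d = t.model_dump(mode="json")
    for b in d["bins"]:
        if b["upper"] == INF:
            b["upper"] = ".inf"
    return d


def _table_from_plain(d: dict) -> RubricTable:
    d = dict(d)
    d["bins"] = [
        {**b, "upper": INF if b.get("upper") in (".inf", "inf", None) else b["upper"]}
        for b in d["bins"]
    ]
    return RubricTable.model_validate(d)


def dump_rubrics(tables: Sequence[RubricTable], path: Union[str, Path]) -> None:
    """Write rubrics to a YAML (or .json) file for auditing or editing."""
    plain = {"phiss_rubrics": [_table_to_plain(t) for t in tables]}
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(plain, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(plain, fh, sort_keys=False)


def load_rubrics(path: Union[str, Path]) -> list[RubricTable]:
    """Load rubrics from a YAML/JSON override file and validate each one.

    Raises :class:`RubricError` if any loaded table fails the structural
    audit, listing every finding.
    """
    path = Path(path)
    with open(path) as fh:
        plain = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(plain, dict) or "phiss_rubrics" not in plain:
        raise RubricError(f"{path}: not a rubric file (missing 'phiss_rubrics' key)")
    tables = [_table_from_plain(d) for d in plain["phiss_rubrics"]]
    problems = [
        f"{r.parameter_id}: {f}" for r in map(validate_rubric, tables) for f in r.findings
    ]
    if problems:
        raise RubricError(f"{path}: invalid rubrics: " + "; ".join(problems))
    return tables
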