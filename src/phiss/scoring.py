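"""Assessment scoring and aggregation into the cumulative PHISS result.

An :class:`Assessment` is one site-time snapshot of raw indicator values for
any subset of the twelve parameters.  :func:`score_assessment` bins each
present value through its rubric and aggregates into a :class:`PhissResult`
with Sphere-category subtotals, the cumulative total (0-100), and
completeness metadata.  Absent parameters are reported missing, never
imputed as zero severity: a partial assessment carries both its raw total
(against 100) and a normalized total (against the maximum attainable over
the answered parameters), and neither silently substitutes for the other.

Longitudinal and cross-event comparison operate on scored results:
consecutive deltas per parameter and in total for one site, and a ranked
table across events with completeness shown alongside.
"""

from __future__ import annotations

import datetime
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .epi import MortalityWindow, WaterSampleSet, excess_deaths, polluted_fraction
from .rubrics import (
    PARAMETER_IDS,
    InadmissibleValueError,
    RubricTable,
    SphereCategory,
    bin_score,
    builtin_rubrics,
)

__all__ = [
    "Assessment",
    "ParameterScore",
    "PhissResult",
    "TrendReport",
    "score_assessment",
    "compare_longitudinal",
    "compare_events",
]


class Assessment(BaseModel):
    """Raw indicator values for one site at one time; any subset may be given.

    The two mortality parameters accept either a :class:`MortalityWindow`
    (rates, population, window) or a pre-computed excess-death count —
    published assessments often quote counts directly.  Water quality
    likewise accepts sample counts or a pre-computed percentage.
    """

    model_config = ConfigDict(extra="forbid")

    site_id: str
    assessed_at: datetime.date
    #: stated assessment window when mortality comes as a pre-computed count;
    #: redundant (and ignored) when a MortalityWindow carries its own window
    period_days: Optional[float] = Field(default=None, gt=0)

    mortality: Optional[MortalityWindow] = None
    excess_deaths_count: Optional[int] = Field(default=None, ge=0)
    under5_mortality: Optional[MortalityWindow] = None
    under5_excess_deaths_count: Optional[int] = Field(default=None, ge=0)
    communicable_cases: Optional[int] = Field(default=None, ge=0)
    injury_cases: Optional[int] = Field(default=None, ge=0)
    healthcare_level: Optional[int] = Field(default=None, ge=0, le=4)
    malnourished_children: Optional[int] = Field(default=None, ge=0)
    displaced_persons: Optional[int] = Field(default=None, ge=0)
    inadequate_space_persons: Optional[int] = Field(default=None, ge=0)
    water_quantity_lpd: Optional[float] = Field(default=None, ge=0)
    water_samples: Optional[WaterSampleSet] = None
    water_polluted_pct: Optional[float] = Field(default=None, ge=0, le=100)
    sanitation_level: Optional[int] = Field(default=None, ge=0, le=5)
    gbv_level: Optional[int] = Field(default=None, ge=0, le=4)

    @model_validator(mode="after")
    def _check_exclusive_and_nonempty(self) -> "Assessment":
        if self.mortality is not None and self.excess_deaths_count is not None:
            raise ValueError(
                f"{self.site_id}: give a mortality window or a pre-computed "
                "excess-death count, not both"
            )
        if self.under5_mortality is not None and self.under5_excess_deaths_count is not None:
            raise ValueError(
                f"{self.site_id}: give an under-5 mortality window or a "
                "pre-computed count, not both"
            )
        if self.water_samples is not None and self.water_polluted_pct is not None:
            raise ValueError(
                f"{self.site_id}: give water samples or a pre-computed "
                "polluted percentage, not both"
            )
        if not any(v is not None for v in self.raw_values().values()):
            raise ValueError(f"{self.site_id}: assessment has no parameters")
        return self

    def raw_values(self) -> dict[str, Optional[float]]:
        """Resolve each parameter to the raw value its rubric consumes (or None)."""
        if self.mortality is not None:
            p1: Optional[float] = excess_deaths(self.mortality)
        else:
            p1 = self.excess_deaths_count
        if self.under5_mortality is not None:
            p2: Optional[float] = excess_deaths(self.under5_mortality)
        else:
            p2 = self.under5_excess_deaths_count
        if self.water_samples is not None:
            p10: Optional[float] = polluted_fraction(self.water_samples)
        else:
            p10 = self.water_polluted_pct
        return {
            "excess_deaths": p1,
            "under5_excess_deaths": p2,
            "communicable_cases": self.communicable_cases,
            "injury_cases": self.injury_cases,
            "healthcare_level": self.healthcare_level,
            "malnourished_children": self.malnourished_children,
            "displaced_persons": self.displaced_persons,
            "inadequate_space_persons": self.inadequate_space_persons,
            "water_quantity_lpd": self.water_quantity_lpd,
            "water_quality_pct": p10,
            "sanitation_level": self.sanitation_level,
            "gbv_level": self.gbv_level,
        }

    def mortality_period_days(self) -> Optional[float]:
        if self.mortality is not None:
            return self.mortality.period_days
        return self.period_days if self.excess_deaths_count is not None else None

    def under5_period_days(self) -> Optional[float]:
        if self.under5_mortality is not None:
            return self.under5_mortality.period_days
        return self.period_days if self.under5_excess_deaths_count is not None else None


class ParameterScore(BaseModel):
    """One parameter's raw value, assigned score, and ceiling."""

    model_config = ConfigDict(frozen=True)

    parameter_id: str
    raw_value: Optional[float] = None
    score: Optional[int] = None
    max_score: int
    present: bool
    category: SphereCategory


class PhissResult(BaseModel):
    """The scored scale for one assessment: twelve parameter scores,
    Sphere-category subtotals, cumulative total, and completeness."""

    site_id: str
    assessed_at: datetime.date
    parameter_scores: list[ParameterScore]
    category_subtotals: dict[str, tuple[int, int]]
    total: int
    total_max_possible: int = 100
    answered_max: int
    completeness: float
    normalized_total: Optional[float] = None
    mortality_period_days: Optional[float] = None
    under5_period_days: Optional[float] = None

    def score_of(self, parameter_id: str) -> Optional[int]:
        for ps in self.parameter_scores:
            if ps.parameter_id == parameter_id:
                return ps.score
        raise KeyError(parameter_id)


def score_assessment(
    a: Assessment, rubrics: Optional[Sequence[RubricTable]] = None
) -> PhissResult:
    """Score one assessment through the twelve rubrics.

    Raises :class:`InadmissibleValueError` naming the parameter if a present
    raw value is outside its rubric's domain.
    """
    tables = {t.parameter_id: t for t in (rubrics if rubrics is not None else builtin_rubrics())}
    missing = [pid for pid in PARAMETER_IDS if pid not in tables]
    if missing:
        raise ValueError(f"rubric set lacks parameters: {missing}")

    raw = a.raw_values()
    scores: list[ParameterScore] = []
    for pid in PARAMETER_IDS:
        t = tables[pid]
        v = raw[pid]
        if v is None:
            scores.append(
                ParameterScore(
                    parameter_id=pid, max_score=t.max_score, present=False, category=t.category
                )
            )
        else:
            scores.append(
                ParameterScore(
                    parameter_id=pid,
                    raw_value=float(v),
                    score=bin_score(t, v),
                    max_score=t.max_score,
                    present=True,
                    category=t.category,
                )
            )

    present = [s for s in scores if s.present]
    if not present:  # Assessment validation forbids this; defend anyway
        raise InadmissibleValueError(f"{a.site_id}: no parameters to score")
    total = sum(s.score for s in present)  # type: ignore[misc]
    answered_max = sum(s.max_score for s in present)
    subtotals: dict[str, tuple[int, int]] = {}
    for cat in SphereCategory:
        in_cat = [s for s in present if s.category is cat]
        subtotals[cat.value] = (
            sum(s.score for s in in_cat),  # type: ignore[misc]
            sum(s.max_score for s in in_cat),
        )

    return PhissResult(
        site_id=a.site_id,
        assessed_at=a.assessed_at,
        parameter_scores=scores,
        category_subtotals=subtotals,
        total=total,
        answered_max=answered_max,
        completeness=len(present) / len(PARAMETER_IDS),
        normalized_total=100.0 * total / answered_max if answered_max else None,
        mortality_period_days=a.mortality_period_days(),
        under5_period_days=a.under5_period_days(),
    )


class TrendReport(BaseModel):
    """Consecutive deltas for one site across ordered assessments.

    ``deltas`` has one row per consecutive pair; negative totals mean
    improvement.  ``warnings`` flags pairs whose mortality windows used
    different lengths — excess-death scores from unequal windows are not
    comparable, so those deltas need standardized periods before
    interpretation.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    site_id: str
    total_deltas: list[int]
    parameter_deltas: list[dict[str, Optional[int]]]
    warnings: list[str]


def compare_longitudinal(results: Sequence[PhissResult]) -> TrendReport:
    """Per-parameter and total deltas between consecutive results for one site."""
    if len(results) < 2:
        raise ValueError("longitudinal comparison needs at least 2 results")
    site_ids = {r.site_id for r in results}
    if len(site_ids) != 1:
        raise ValueError(f"longitudinal comparison mixes sites: {sorted(site_ids)}")

    total_deltas: list[int] = []
    parameter_deltas: list[dict[str, Optional[int]]] = []
    warnings: list[str] = []
    for i, (prev, nxt) in enumerate(zip(results, results[1:])):
        total_deltas.append(nxt.total - prev.total)
        deltas: dict[str, Optional[int]] = {}
        for pid in PARAMETER_IDS:
            s0, s1 = prev.score_of(pid), nxt.score_of(pid)
            deltas[pid] = None if s0 is None or s1 is None else s1 - s0
        parameter_deltas.append(deltas)
        for pid, attr in [
            ("excess_deaths", "mortality_period_days"),
            ("under5_excess_deaths", "under5_period_days"),
        ]:
            d0, d1 = getattr(prev, attr), getattr(nxt, attr)
            if d0 is not None and d1 is not None and d0 != d1:
                warnings.append(
                    f"assessments {i} and {i + 1}: {pid} windows differ "
                    f"({d0:g} vs {d1:g} days); scores not comparable without "
                    "a standardized period"
                )
    return TrendReport(
        site_id=results[0].site_id,
        total_deltas=total_deltas,
        parameter_deltas=parameter_deltas,
        warnings=warnings,
    )


def compare_events(results: Sequence[PhissResult]) -> pd.DataFrame:
    """Rank events by total score, most severe first.

    Ties break by normalized total (severity relative to the answered
    maximum), then by site id lexically.  Completeness is reported alongside
    so unequally complete assessments are not compared naively.
    """
    if len(results) < 2:
        raise ValueError("event comparison needs at least 2 results")
    rows = [
        {
            "site_id": r.site_id,
            "assessed_at": r.assessed_at.isoformat(),
            "total": r.total,
            "answered_max": r.answered_max,
            "normalized_total": round(r.normalized_total, 2)
            if r.normalized_total is not None
            else None,
            "completeness": round(r.completeness, 4),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["total", "normalized_total", "site_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df
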