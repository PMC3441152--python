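"""Worked examples from the source tables and synthetic scenario generation.

The worked examples are the published per-parameter illustrations (a raw
value, the score it receives, and a citation note); they are shipped as a
JSON data file and exercised by ``phiss demo``.  They are parameter
fragments, not full assessments — each historical event was scored on one
parameter for illustration, never cumulatively.

The scenario generator fabricates plausible multi-visit assessments for one
synthetic site so that scoring, comparison and I/O paths can be tested
without field data.  It makes no claim of epidemiological realism; it
exists to exercise code paths and severity monotonicity.
"""

from __future__ import annotations

import datetime
import json
from enum import Enum
from importlib import resources
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .epi import MortalityWindow, WaterSampleSet
from .scoring import Assessment

__all__ = [
    "WorkedExample",
    "Severity",
    "ScenarioSpec",
    "worked_examples",
    "builtin_assessment_path",
    "generate_scenario",
]


class WorkedExample(BaseModel):
    """One published per-parameter illustration: value, expected score, source."""

    model_config = ConfigDict(frozen=True)

    name: str
    parameter_id: str
    raw_value: float
    expected_score: int
    citation: str


def worked_examples() -> list[WorkedExample]:
    """The shipped worked examples (one per published illustration)."""
    text = resources.files("phiss.data").joinpath("worked_examples.json").read_text()
    doc = json.loads(text)
    return [WorkedExample.model_validate(d) for d in doc["worked_examples"]]


def builtin_assessment_path() -> str:
    """Path of the shipped example assessment document (Haiti 2010 fragment)."""
    return str(resources.files("phiss.data").joinpath("haiti_2010.json"))


# ---------------------------------------------------------------------------
# synthetic scenarios


class Severity(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    CATASTROPHIC = "catastrophic"


_SEVERITY_INDEX = {s: i for i, s in enumerate(Severity)}

# Scenario calibration per severity level.  Mortality baselines sit at the
# emergency benchmarks (CMR 1/10,000/day, U5MR 2/10,000/day); the excess
# factor scales the crisis mortality above baseline.  Count parameters are
# Poisson with means proportional to the affected population; water
# quantity decays with severity; ordinal levels step up with severity.
_EXCESS_FACTOR = [0.3, 1.0, 3.0, 8.0]
_CASE_FRACTION = {
    "communicable_cases": [0.002, 0.01, 0.05, 0.15],
    "injury_cases": [0.001, 0.005, 0.03, 0.10],
    "displaced_persons": [0.01, 0.05, 0.20, 0.50],
    "inadequate_space_persons": [0.005, 0.03, 0.12, 0.35],
}
_MALNUTRITION_FRACTION = [0.01, 0.05, 0.15, 0.30]  # of the under-5 population
_WATER_LPD = [13.0, 8.5, 4.0, 1.5]
_POLLUTED_P = [0.05, 0.25, 0.55, 0.92]
_HEALTHCARE = [1, 2, 3, 4]
_SANITATION = [1, 2, 4, 5]
_GBV = [0, 1, 3, 4]
_RECOVERY = 0.85  # per-visit multiplicative easing of rates/fractions


class ScenarioSpec(BaseModel):
    """Parameters of one synthetic longitudinal scenario."""

    model_config = ConfigDict(frozen=True)

    severity_level: Severity
    affected_population: int = Field(default=100_000, gt=0)
    under5_fraction: float = Field(default=0.17, gt=0, lt=1)
    n_assessments: int = Field(default=3, ge=1)
    interval_days: int = Field(default=30, gt=0)
    seed: int = 0
    site_id: str = "synthetic-site"
    start_date: datetime.date = datetime.date(2020, 1, 1)


def generate_scenario(spec: ScenarioSpec) -> list[Assessment]:
    """Generate ``n_assessments`` sequential assessments for one synthetic site.

    The same seed reproduces identical output.  All stochastic draws are
    made through inverse-CDF transforms of severity-independent uniforms, so
    for a fixed seed every raw value — and hence the total score — is
    monotone in the severity level by construction.
    """
    rng = np.random.default_rng(spec.seed)
    s = _SEVERITY_INDEX[spec.severity_level]
    pop = spec.affected_population
    u5_pop = spec.under5_fraction * pop

    out: list[Assessment] = []
    for visit in range(spec.n_assessments):
        ease = _RECOVERY**visit
        # one lognormal noise factor per rate-like quantity, shared across
        # severity levels for a given seed/visit
        noise = np.exp(rng.normal(0.0, 0.2, size=3))
        u = rng.uniform(size=6)  # uniforms for count inverse-CDF draws
        jitter = int(rng.integers(-1, 2))

        cmr_base = 1.0
        u5mr_base = 2.0
        mortality = MortalityWindow(
            observed_rate=cmr_base * (1 + _EXCESS_FACTOR[s] * ease * noise[0]),
            baseline_rate=cmr_base,
            population_at_risk=pop,
            period_days=spec.interval_days,
        )
        under5 = MortalityWindow(
            observed_rate=u5mr_base * (1 + _EXCESS_FACTOR[s] * ease * noise[1]),
            baseline_rate=u5mr_base,
            population_at_risk=u5_pop,
            period_days=spec.interval_days,
        )

        def pois(mean: float, q: float) -> int:
            return int(stats.poisson.ppf(q, max(mean, 1e-9)))

        counts = {
            k: pois(_CASE_FRACTION[k][s] * ease * pop, q)
            for k, q in zip(_CASE_FRACTION, u)
        }
        malnourished = pois(_MALNUTRITION_FRACTION[s] * ease * u5_pop, u[4])
        n_samples = 30
        n_polluted = int(stats.binom.ppf(u[5], n_samples, _POLLUTED_P[s] * ease))

        water_lpd = float(_WATER_LPD[s] / ease * noise[2])

        def level(base: list[int], ceiling: int) -> int:
            return int(np.clip(base[s] + jitter, 0, ceiling))

        out.append(
            Assessment(
                site_id=spec.site_id,
                assessed_at=spec.start_date + datetime.timedelta(days=visit * spec.interval_days),
                mortality=mortality,
                under5_mortality=under5,
                communicable_cases=counts["communicable_cases"],
                injury_cases=counts["injury_cases"],
                healthcare_level=level(_HEALTHCARE, 4),
                malnourished_children=malnourished,
                displaced_persons=counts["displaced_persons"],
                inadequate_space_persons=counts["inadequate_space_persons"],
                water_quantity_lpd=water_lpd,
                water_samples=WaterSampleSet(n_samples=n_samples, n_polluted=n_polluted),
                sanitation_level=level(_SANITATION, 5),
                gbv_level=level(_GBV, 4),
            )
        )
    return out
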