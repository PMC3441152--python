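"""Derived raw quantities: excess deaths and water-sample contamination.

Excess mortality — deaths attributable to the crisis above the baseline
non-crisis expectation — is the product of the rate difference, the
population at risk and the time window:

    excess = max(0, CMR_obs - CMR_base) / denominator x population x days

with rates expressed per ``denominator`` persons per day (10,000 by
convention; the emergency benchmarks are CMR 1/10,000/day and U5MR
2/10,000/day).  The same formula applies to under-5 excess deaths with the
under-5 population at risk.  Negative excess clamps to zero: the scale
measures impact, not improvement.  The result rounds half-up to an integer
count, since the mortality rubrics bin integer death counts.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MortalityWindow",
    "WaterSampleSet",
    "excess_deaths",
    "under5_excess_deaths",
    "polluted_fraction",
]


class MortalityWindow(BaseModel):
    """Mortality rates over one assessment window.

    ``observed_rate`` and ``baseline_rate`` are deaths per ``denominator``
    persons per day.  ``population_at_risk`` is the whole affected
    population for crude mortality, or the under-5 population for under-5
    mortality.  The time window is an explicit input with no default: it
    must be stated (e.g. onset-to-assessment, or the last month) for scores
    to be comparable across assessments.
    """

    model_config = ConfigDict(frozen=True)

    observed_rate: float = Field(ge=0)
    baseline_rate: float = Field(ge=0)
    population_at_risk: float = Field(ge=0)
    period_days: float = Field(gt=0)
    denominator: float = Field(default=10_000, gt=0)


class WaterSampleSet(BaseModel):
    """Water-source test results: sources sampled and sources polluted.

    A source counts as polluted when it exceeds 10 fecal coliforms per
    100 ml (OFDA guideline).
    """

    model_config = ConfigDict(frozen=True)

    n_samples: int = Field(gt=0, description="water sources tested; must be > 0")
    n_polluted: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_counts(self) -> "WaterSampleSet":
        if self.n_polluted > self.n_samples:
            raise ValueError(
                f"polluted sources ({self.n_polluted}) exceed sources tested ({self.n_samples})"
            )
        return self


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def excess_deaths(w: MortalityWindow) -> int:
    """Excess death count for a mortality window; never negative."""
    # multiply before dividing so exact halves survive floating point
    excess = max(0.0, w.observed_rate - w.baseline_rate) * w.population_at_risk
    return _round_half_up(excess * w.period_days / w.denominator)


def under5_excess_deaths(w: MortalityWindow) -> int:
    """Under-5 excess death count; ``w.population_at_risk`` is the under-5 population."""
    return excess_deaths(w)


def polluted_fraction(s: WaterSampleSet) -> float:
    """Percentage of sampled water sources that are polluted, in [0, 100].

    Not rounded: the exact fraction feeds the water-quality rubric.
    """
    return 100.0 * s.n_polluted / s.n_samples
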