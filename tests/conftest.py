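import datetime

import pytest

from phiss import Assessment, MortalityWindow, WaterSampleSet, builtin_rubrics


@pytest.fixture(scope="session")
def rubrics():
    """The twelve shipped rubrics, keyed by parameter id."""
    return {t.parameter_id: t for t in builtin_rubrics()}


#: least-severe and most-severe admissible raw values per parameter
LEAST_SEVERE = {
    "excess_deaths_count": 0,
    "under5_excess_deaths_count": 0,
    "communicable_cases": 0,
    "injury_cases": 0,
    "healthcare_level": 0,
    "malnourished_children": 0,
    "displaced_persons": 0,
    "inadequate_space_persons": 0,
    "water_quantity_lpd": 20.0,
    "water_polluted_pct": 0.0,
    "sanitation_level": 0,
    "gbv_level": 0,
}
MOST_SEVERE = {
    "excess_deaths_count": 300_000,
    "under5_excess_deaths_count": 60_000,
    "communicable_cases": 60_000,
    "injury_cases": 300_000,
    "healthcare_level": 4,
    "malnourished_children": 60_000,
    "displaced_persons": 1_000_000,
    "inadequate_space_persons": 200_000,
    "water_quantity_lpd": 0.0,
    "water_polluted_pct": 100.0,
    "sanitation_level": 5,
    "gbv_level": 4,
}


def make_assessment(site_id="test-site", date=datetime.date(2020, 6, 1), **values):
    return Assessment(site_id=site_id, assessed_at=date, **values)


@pytest.fixture
def full_assessment():
    """An assessment with every parameter present, via the derived inputs."""
    return make_assessment(
        mortality=MortalityWindow(
            observed_rate=2.0, baseline_rate=1.0, population_at_risk=100_000, period_days=30
        ),
        under5_mortality=MortalityWindow(
            observed_rate=4.0, baseline_rate=2.0, population_at_risk=20_000, period_days=30
        ),
        communicable_cases=3_342,
        injury_cases=12_000,
        healthcare_level=3,
        malnourished_children=1_500,
        displaced_persons=80_000,
        inadequate_space_persons=25_000,
        water_quantity_lpd=6.0,
        water_samples=WaterSampleSet(n_samples=240, n_polluted=109),
        sanitation_level=4,
        gbv_level=2,
    )
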