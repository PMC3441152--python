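"""Structural and boundary behaviour of the twelve shipped rubrics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phiss import (
    PARAMETER_IDS,
    InadmissibleValueError,
    RubricError,
    RubricTable,
    ScoreBin,
    bin_score,
    builtin_rubrics,
    dump_rubrics,
    load_rubrics,
    validate_rubric,
)
from phiss.rubrics import Direction, MeasureKind, SphereCategory


def linear_scan_score(table, value):
    """Independent oracle: walk every bin and return the single match."""
    matches = [b.score for b in table.bins if b.contains(float(value))]
    assert len(matches) == 1, f"{table.parameter_id}: {value} matched {len(matches)} bins"
    return matches[0]


def admissible_values(table, rng, n):
    """Random admissible raw values for one rubric, spanning all magnitudes."""
    if table.measure_kind is MeasureKind.ORDINAL:
        codes = [lvl.level_code for lvl in table.levels]
        return rng.choice(codes, size=n)
    if table.measure_kind is MeasureKind.PERCENTAGE:
        return rng.uniform(0, 100, size=n)
    if table.measure_kind is MeasureKind.RATE_PER_PERSON_DAY:
        return rng.uniform(0, 30, size=n)
    # counts: log-uniform over the full dynamic range of the tables
    return (10 ** rng.uniform(0, 6.5, size=n)).astype(int)


EXPECTED_MAX = {
    "excess_deaths": 10,
    "under5_excess_deaths": 10,
    "communicable_cases": 10,
    "injury_cases": 10,
    "healthcare_level": 4,
    "malnourished_children": 10,
    "displaced_persons": 9,
    "inadequate_space_persons": 9,
    "water_quantity_lpd": 9,
    "water_quality_pct": 10,
    "sanitation_level": 5,
    "gbv_level": 4,
}


def test_twelve_rubrics_in_order(rubrics):
    assert [t.parameter_id for t in builtin_rubrics()] == list(PARAMETER_IDS)
    assert len(rubrics) == 12


def test_max_scores_and_ceiling(rubrics):
    assert {pid: t.max_score for pid, t in rubrics.items()} == EXPECTED_MAX
    assert sum(t.max_score for t in rubrics.values()) == 100


def test_shipped_rubrics_pass_structural_audit(rubrics):
    for t in rubrics.values():
        report = validate_rubric(t)
        assert report.ok, f"{t.parameter_id}: {report.findings}"


def test_category_mapping(rubrics):
    by_cat = {
        "health": ["excess_deaths", "under5_excess_deaths", "communicable_cases",
                   "injury_cases", "healthcare_level", "gbv_level"],
        "food-nutrition": ["malnourished_children"],
        "shelter": ["displaced_persons", "inadequate_space_persons"],
        "water-sanitation": ["water_quantity_lpd", "water_quality_pct", "sanitation_level"],
    }
    for cat, pids in by_cat.items():
        for pid in pids:
            assert rubrics[pid].category.value == cat


@pytest.mark.parametrize(
    "pid, value, expected",
    [
        # published example rows and example sentences
        ("excess_deaths", 222_570, 9),       # Haiti 2010
        ("excess_deaths", 300_000, 10),      # Bangladesh 1970, ceiling
        ("excess_deaths", 67, 1),            # Greece 2007
        ("excess_deaths", 73_338, 7),        # Pakistan 2005
        ("excess_deaths", 0, 0),
        ("under5_excess_deaths", 46_900, 8), # Iraq 1991
        ("injury_cases", 12_000, 5),         # Chile 2010
        ("injury_cases", 200_000, 9),        # India 1984
        ("injury_cases", 300_000, 10),       # Haiti 2010
        ("malnourished_children", 63_000, 10),  # Niger 2005
        ("water_quality_pct", 45.2, 5),      # Darfur 2009
        ("water_quantity_lpd", 0.2, 9),      # Rwanda 1994
        ("inadequate_space_persons", 0, 0),  # Kibeho 1994
        ("healthcare_level", 4, 4),          # Haiti 2010 acute phase
        ("gbv_level", 4, 4),                 # Bosnia, systematic
    ],
)
def test_published_examples(rubrics, pid, value, expected):
    assert bin_score(rubrics[pid], value) == expected


def count_edge_cases():
    """Every printed bin edge of the count tables, with its adjacent scores."""
    edges = {
        "excess_deaths": [10, 100, 1_000, 5_000, 10_000, 20_000, 50_000, 100_000,
                          200_000, 300_000],
        "under5_excess_deaths": [10, 100, 1_000, 5_000, 10_000, 20_000, 30_000,
                                 40_000, 50_000, 60_000],
        "communicable_cases": [20, 100, 1_000, 5_000, 10_000, 20_000, 30_000,
                               40_000, 50_000, 60_000],
        "injury_cases": [20, 100, 1_000, 5_000, 10_000, 20_000, 50_000, 100_000,
                         200_000, 300_000],
        "malnourished_children": [20, 100, 1_000, 5_000, 10_000, 20_000, 30_000,
                                  40_000, 50_000, 60_000],
        "displaced_persons": [20, 100, 1_000, 10_000, 50_000, 100_000, 200_000,
                              500_000, 1_000_000],
        "inadequate_space_persons": [20, 100, 1_000, 5_000, 10_000, 20_000,
                                     50_000, 100_000, 200_000],
    }
    for pid, es in edges.items():
        for k, e in enumerate(es, start=1):
            yield pid, e, k        # the edge itself starts the higher bin
            yield pid, e - 1, k - 1  # one below the edge ends the lower bin


@pytest.mark.parametrize("pid, value, expected", sorted(count_edge_cases()))
def test_count_bin_edges(rubrics, pid, value, expected):
    assert bin_score(rubrics[pid], value) == expected


@pytest.mark.parametrize(
    "value, expected",
    [
        (0.0, 9), (2.4, 9), (2.5, 8), (3.4, 8), (3.5, 7), (4.5, 6), (5.5, 5),
        (6.5, 4), (7.4, 4), (7.5, 3), (9.9, 3), (10.0, 2), (12.4, 2),
        (12.5, 1), (15.0, 1), (15.000001, 0), (100.0, 0),
    ],
)
def test_water_quantity_bands(rubrics, value, expected):
    """Severity falls as liters/person/day rise; the 12.5-15 band closes at 15."""
    assert bin_score(rubrics["water_quantity_lpd"], value) == expected


@pytest.mark.parametrize(
    "value, expected",
    [(0.0, 0), (0.01, 1), (9.9, 1), (10.0, 2), (45.2, 5), (89.9, 9),
     (90.0, 10), (100.0, 10)],
)
def test_water_quality_bands(rubrics, value, expected):
    assert bin_score(rubrics["water_quality_pct"], value) == expected


@pytest.mark.parametrize(
    "pid, bad",
    [
        ("excess_deaths", -1),
        ("excess_deaths", 10.5),
        ("water_quality_pct", 101.0),
        ("water_quantity_lpd", -0.1),
        ("healthcare_level", 5),
        ("sanitation_level", 6),
        ("gbv_level", 2.5),
        ("excess_deaths", math.nan),
    ],
)
def test_inadmissible_values_name_the_parameter(rubrics, pid, bad):
    with pytest.raises(InadmissibleValueError, match=pid):
        bin_score(rubrics[pid], bad)


def test_coverage_matches_linear_scan_oracle(rubrics):
    """Bisection lookup agrees with a full linear scan on random values."""
    import numpy as np

    rng = np.random.default_rng(2012)
    for t in rubrics.values():
        for v in admissible_values(t, rng, 500):
            v = v.item()
            assert bin_score(t, v) == linear_scan_score(t, v)


@settings(max_examples=200, deadline=None)
@given(
    st.sampled_from([p for p in PARAMETER_IDS
                     if p not in ("healthcare_level", "sanitation_level", "gbv_level")]),
    st.integers(min_value=0, max_value=3_000_000),
    st.integers(min_value=0, max_value=3_000_000),
)
def test_monotonicity_along_raw_axis(pid, a, b):
    """Higher raw severity never lowers the score (reversed for water quantity)."""
    table = {t.parameter_id: t for t in builtin_rubrics()}[pid]
    lo, hi = sorted((a, b))
    if table.measure_kind is MeasureKind.PERCENTAGE:
        lo, hi = 100 * lo / 3_000_000, 100 * hi / 3_000_000
    elif table.measure_kind is MeasureKind.RATE_PER_PERSON_DAY:
        lo, hi = 30 * lo / 3_000_000, 30 * hi / 3_000_000
    s_lo, s_hi = bin_score(table, lo), bin_score(table, hi)
    if table.direction is Direction.DECREASING:
        assert s_lo >= s_hi
    else:
        assert s_lo <= s_hi


def test_ordinal_level_catalogues(rubrics):
    hc = rubrics["healthcare_level"].levels
    assert [l.level_code for l in hc] == [0, 1, 2, 3, 4]
    assert hc[0].description.startswith("All levels of health care system are intact")
    assert hc[4].description == "All levels of health care disrupted"
    sa = rubrics["sanitation_level"].levels
    assert [l.level_code for l in sa] == [0, 1, 2, 3, 4, 5]
    assert sa[5].description.startswith("Complete absence of any system")
    gbv = rubrics["gbv_level"].levels
    assert [l.level_code for l in gbv] == [0, 1, 2, 3, 4]
    assert gbv[4].description == "Systematic gender-based violence"


def test_validate_rubric_reports_constructed_violations():
    bad = RubricTable(
        parameter_id="constructed",
        name="constructed overlap",
        measure_kind=MeasureKind.COUNT,
        category=SphereCategory.HEALTH,
        bins=(
            ScoreBin(lower=0, upper=10, score=0),
            ScoreBin(lower=5, upper=20, score=1),
            ScoreBin(lower=30, upper=math.inf, score=3),
        ),
        max_score=2,
    )
    report = validate_rubric(bad)
    assert not report.ok
    joined = " ".join(report.findings)
    assert "overlap" in joined
    assert "gap" in joined
    assert "max_score" in joined


def test_rubric_yaml_roundtrip(tmp_path, rubrics):
    path = tmp_path / "rubrics.yaml"
    dump_rubrics(list(rubrics.values()), path)
    loaded = load_rubrics(path)
    assert loaded == builtin_rubrics()


def test_rubric_json_roundtrip(tmp_path, rubrics):
    path = tmp_path / "rubrics.json"
    dump_rubrics(list(rubrics.values()), path)
    assert load_rubrics(path) == builtin_rubrics()


def test_load_rejects_invalid_override(tmp_path):
    path = tmp_path / "bad.yaml"
    tables = builtin_rubrics()
    import yaml

    from phiss.rubrics import _table_to_plain

    plain = {"phiss_rubrics": [_table_to_plain(t) for t in tables]}
    plain["phiss_rubrics"][0]["max_score"] = 7  # no longer the largest bin score
    path.write_text(yaml.safe_dump(plain))
    with pytest.raises(RubricError, match="max_score"):
        load_rubrics(path)
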