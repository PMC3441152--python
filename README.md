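# phiss — the Public Health Impact Severity Scale

`phiss` implements the Public Health Impact Severity Scale (PHISS), a
quantitative 0–100 index of the public health impact of a Complex
Humanitarian Emergency (CHE). It is aimed at field epidemiologists,
humanitarian assessment teams and response planners who need a single
reproducible number — with per-sector detail — out of the raw indicators a
rapid assessment collects.

## The scale

Twelve parameters, grounded in the Sphere Project "Minimum Standards for
Disaster Response" (health, food & nutrition, shelter, water & sanitation),
each map a raw value onto an integer severity score through a fixed scoring
table:

| # | parameter | input | max |
|---|---|---|---:|
| 1 | excess deaths | count (or CMR window, see below) | 10 |
| 2 | under-5 excess deaths | count (or U5MR window) | 10 |
| 3 | acute communicable-disease cases | count | 10 |
| 4 | traumatic/chemical/radiological injuries | count | 10 |
| 5 | level of health-care services | ordinal 0–4 | 4 |
| 6 | children 6–59 months with acute malnutrition (WfH < −2 Z or edema) | count | 10 |
| 7 | displaced persons (IDPs + refugees) | count | 9 |
| 8 | persons with inadequate living space (< 45 m² site / 3.5 m² covered) | count | 9 |
| 9 | water quantity | liters/person/day | 9 |
| 10 | water quality | % sources > 10 fecal coliforms/100 ml | 10 |
| 11 | level of sanitation facilities | ordinal 0–5 | 5 |
| 12 | gender-based violence | ordinal 0–4 | 4 |

The maxima sum to 100, so the cumulative score runs from 0 (no measurable
impact) to 100 (every parameter at its ceiling). Mortality enters as
*excess deaths* — the count attributable to the crisis above the non-crisis
baseline:

```
excess = max(0, CMR_obs − CMR_base) / 10,000 × population at risk × days
```

with rates per 10,000 persons per day (emergency benchmarks: CMR
1/10,000/day, U5MR 2/10,000/day). Count floors follow the CRED/EM-DAT
disaster-registry entry criteria (≥ 10 killed; the five affected-person
parameters each floor at 20, jointly matching ≥ 100 affected). Severity
rises with every raw value except water quantity, where less water is
worse.

Missing parameters are reported as missing, never scored zero: a partial
assessment carries its raw total (against 100), the answered maximum, and a
normalized total against that maximum.

## Worked example

```python
import datetime
import phiss

a = phiss.Assessment(
    site_id="camp-east", assessed_at=datetime.date(2020, 3, 1),
    mortality=phiss.MortalityWindow(observed_rate=2.0, baseline_rate=1.0,
                                    population_at_risk=100_000, period_days=30),
    malnourished_children=1_500,
    water_quantity_lpd=6.0,
    water_samples=phiss.WaterSampleSet(n_samples=240, n_polluted=109),
    sanitation_level=4,
)
r = phiss.score_assessment(a)
print(r.total, r.answered_max, round(r.normalized_total, 1))
for ps in r.parameter_scores:
    if ps.present:
        print(f"{ps.parameter_id}: raw {ps.raw_value:g} -> {ps.score}/{ps.max_score}")
```

prints

```
19 44 43.2
excess_deaths: raw 300 -> 2/10
malnourished_children: raw 1500 -> 3/10
water_quantity_lpd: raw 6 -> 5/9
water_quality_pct: raw 45.4167 -> 5/10
sanitation_level: raw 4 -> 4/5
```

The mortality window yields (2−1)/10,000 × 100,000 × 30 = 300 excess
deaths, which falls in the 100–999 band (score 2). 109 of 240 water sources
polluted is 45.4%, in the 40–49.9% band (score 5). Five of twelve
parameters were answered, so the total of 19 is reported against both the
full ceiling of 100 and the answered maximum of 44 (normalized 43.2).

## Command line

```
phiss score assessment.json --format md      # one assessment -> report
phiss batch assessments.csv                  # CSV batch -> ranked comparison
phiss demo                                   # re-score the shipped worked examples
phiss validate                               # structural audit of the rubrics
phiss compare report1.json report2.json ...  # longitudinal deltas for one site
```

All subcommands accept `--rubrics FILE` to load an audited YAML/JSON
override of the scoring tables (`phiss.dump_rubrics` writes the shipped
ones as a starting point). `phiss demo` exits non-zero if any published
worked example fails to reproduce; `phiss compare` warns when two
assessments used different mortality windows, which makes their
excess-death scores non-comparable.

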