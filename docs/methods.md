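# Methods

## The scale

PHISS scores one site-time assessment on up to twelve parameters and sums
the per-parameter scores into a cumulative severity total. Each parameter
is an interval-binning rubric: an ordered, gap-free, overlap-free partition
of the admissible raw domain, each cell carrying an integer severity score.
The parameter maxima are 10, 10, 10, 10, 4, 10, 9, 9, 9, 10, 5, 4 and sum
to exactly 100, which fixes the scale's ceiling. Scores are unweighted
beyond the differing maxima; the unequal ceilings are the intended
weighting.

Assumptions worth stating plainly: the rubric cut-points are consensus
choices anchored where possible in published criteria (CRED/EM-DAT entry
thresholds for the count floors and the death-count ceiling of 300,000 from
the 1970 Bangladesh cyclone; Sphere water-supply guidance for the
liters/person/day bands; OFDA's >10 fecal coliforms/100 ml pollution
threshold; Sphere staffing levels as the ordinal health-care ladder). The
scale is a severity index, not a validated measurement instrument, and the
package treats the tables as fixed data, not as something to re-calibrate.

## Encoding choices for the printed tables

The printed tables leave a few conventions implicit; the package resolves
them as follows, and `validate_rubric` enforces the result structurally
(full coverage, no overlaps, monotone scores, declared maximum equals the
largest bin score):

- **Count bins are half-open integer ranges.** A printed "20–99" is
  encoded `[20, 100)`, so every non-negative integer lands in exactly one
  bin.
- **Death-count floors are 10.** The two mortality tables' accompanying
  text fixes the floor at 10 deaths (the CRED ≥10-killed criterion), so
  they are encoded `<10 → 0, 10–99 → 1`. The five affected-person counts
  floor at 20 each, five of them jointly matching the CRED ≥100-affected
  criterion.
- **Displaced persons "10,000–49,000"** is read as 10,000–49,999: the
  adjacent bin starts at 50,000, so the printed upper bound is a
  typographical truncation. The table's maximum for this parameter is 9;
  that is the value that preserves the 100-point ceiling, so the ceiling
  row scores 9 even though one prose illustration suggests 10.
- **Water quantity** prints one-decimal band labels ("10–12.4",
  "7.5–9.9"); these are rounded labels of contiguous real intervals, so
  the bands are encoded half-open (`[7.5, 10)`, `[10, 12.5)`, …) with the
  "12.5–15" band closed at 15 and ">15" open at 15. Severity decreases
  with the raw value for this parameter only.
- **Water quality** scores 0 only for exactly 0% polluted samples; any
  positive fraction scores at least 1. The top band ">90%" is encoded
  `≥ 90` so that exactly 90% is covered, the severity-conservative
  reading.
- **Category mapping.** Sphere-category subtotals need a per-parameter
  category: parameters 1–5 are assigned to health, 6 to food & nutrition,
  7–8 to shelter, 9–11 to water & sanitation, following the order of
  presentation against the four categories. Gender-based violence has no
  stated category and is assigned to health. The mapping lives on each
  rubric table and is overridable via a rubric file.
- The results enumeration lists "level of healthcare services" twice; it
  is implemented once (parameter 5), treating the repeat as editorial.

## Excess mortality

Excess deaths are `max(0, observed − baseline) × population × days /
denominator`, with rates per `denominator` persons per day (default
10,000). Choices the formula's prose leaves open:

- **Clamping:** negative excess (a population healthier than baseline)
  clamps to 0 — the scale measures impact, not improvement.
- **Rounding:** the product rounds half-up to an integer count, since the
  rubrics bin integer deaths. Multiplication precedes the division by the
  denominator so that exact halves survive floating point.
- **The time window is mandatory and explicit.** No default window is
  imposed; assessments must state it (onset-to-assessment and last-month
  are the common conventions). Longitudinal comparison flags any pair of
  results whose mortality windows differ, because excess-death scores from
  unequal windows are not comparable.
- Published excess-death *counts* are accepted directly as an alternative
  to rate inputs, since real assessments often quote counts.

## Partial assessments and comparison

An absent parameter contributes nothing: it is excluded from the total, the
answered maximum and the category subtotals, and reported as missing. The
result carries completeness (fraction of 12 answered), the answered maximum,
and a normalized total `100 × total / answered_max`; raw and normalized
views are both surfaced and neither substitutes for the other. Cross-event
ranking orders by raw total, breaking ties by normalized total and then
site id lexically — artifact policy, chosen so sparser-but-relatively-worse
assessments surface — and always reports completeness alongside.

## Synthetic scenarios

`generate_scenario` fabricates longitudinal assessments for one synthetic
site at four severity levels (mild, moderate, severe, catastrophic). It
emulates the *shape* of assessment data, not its epidemiology: mortality
baselines sit at the emergency benchmarks (CMR 1/10,000/day, U5MR
2/10,000/day) with observed rates a severity-dependent multiple above
baseline under lognormal noise (σ = 0.2); count parameters are Poisson with
means proportional to the affected population (case fractions rising with
severity); water-sample pollution is binomial over 30 sources; water
quantity decays with severity; ordinal levels step up with severity with a
shared ±1 jitter; and each later visit eases rates by a recovery factor of
0.85. All stochastic draws go through inverse-CDF transforms of
severity-independent uniforms, so for a fixed seed every raw value — hence
the total — is monotone in the severity level by construction. Default
problem sizes (population 100,000, three visits at 30-day intervals) keep
generation and scoring instantaneous.

Passing tests on these scenarios therefore demonstrate engine correctness
(admissibility, conservation, monotonicity, determinism), not that the
generator resembles any real emergency: real data have correlated
indicators, reporting delays, and measurement error that the generator does
not model.

## Numerical and degenerate-input conventions

- Bin lookup is by bisection on lower bounds with a one-step adjustment
  for boundary inclusivity; tests cross-check it against a linear scan of
  every bin.
- Counts must be non-negative integers; percentages live in [0, 100];
  ordinal codes must be defined levels. Violations raise a domain error
  naming the parameter.
- An assessment with zero parameters is rejected at validation, as are
  simultaneous rate-and-count inputs for the same parameter.
- Reports are deterministic: sorted JSON keys, fixed number formats, so
  identical inputs are byte-identical.

## Known limitations

- No estimation of mortality rates from survey data, no confidence
  intervals on excess deaths or scores, no imputation of missing
  parameters, and no geographic aggregation across sites.
- The scale itself is unvalidated as an instrument; this package makes its
  arithmetic reproducible, which is a precondition for - not a substitute
  for - validation studies.
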