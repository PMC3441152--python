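"""File formats: assessment documents in, score reports out.

JSON is the canonical single-assessment format; CSV is the batch format
(one assessment per row, flat column dictionary below).  Reports render as
JSON (lossless round-trip of the result), Markdown (per-parameter table
mirroring the scoring-table layout) or CSV.  Output is deterministic:
sorted keys, fixed number formatting, so identical inputs give
byte-identical reports.

CSV column dictionary (unknown columns are rejected; blank cells = absent):

    site_id            required text
    assessed_at        required ISO-8601 date
    period_days        assessment window in days (required with rate inputs)
    cmr_observed, cmr_baseline          crude mortality, per rate_denominator/day
    population_at_risk                  persons exposed (with cmr_*)
    u5mr_observed, u5mr_baseline        under-5 mortality, same units
    under5_population                   children under 5 (with u5mr_*)
    rate_denominator                    rate denominator persons (default 10000)
    excess_deaths_count, under5_excess_deaths_count   pre-computed counts
    communicable_cases, injury_cases, malnourished_children,
    displaced_persons, inadequate_space_persons       counts of persons
    healthcare_level   ordinal 0-4      sanitation_level  ordinal 0-5
    gbv_level          ordinal 0-4
    water_quantity_lpd liters/person/day
    water_samples_tested, water_samples_polluted      source counts
    water_polluted_pct pre-computed percentage
"""

from __future__ import annotations

import json
import math
import sys
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import pandas as pd
from pydantic import ValidationError

from .epi import MortalityWindow, WaterSampleSet
from .rubrics import PARAMETER_IDS
from .scoring import Assessment, PhissResult

__all__ = [
    "SCHEMA_VERSION",
    "AssessmentParseError",
    "read_assessment",
    "read_assessment_json",
    "read_assessment_csv",
    "write_report",
    "write_assessment_json",
    "read_report_json",
]

SCHEMA_VERSION = "1.0"

_CSV_COLUMNS = {
    "site_id",
    "assessed_at",
    "period_days",
    "cmr_observed",
    "cmr_baseline",
    "population_at_risk",
    "u5mr_observed",
    "u5mr_baseline",
    "under5_population",
    "rate_denominator",
    "excess_deaths_count",
    "under5_excess_deaths_count",
    "communicable_cases",
    "injury_cases",
    "healthcare_level",
    "malnourished_children",
    "displaced_persons",
    "inadequate_space_persons",
    "water_quantity_lpd",
    "water_samples_tested",
    "water_samples_polluted",
    "water_polluted_pct",
    "sanitation_level",
    "gbv_level",
}

_INT_FIELDS = {
    "excess_deaths_count",
    "under5_excess_deaths_count",
    "communicable_cases",
    "injury_cases",
    "healthcare_level",
    "malnourished_children",
    "displaced_persons",
    "inadequate_space_persons",
    "sanitation_level",
    "gbv_level",
}


class AssessmentParseError(ValueError):
    """A document failed to parse or validate; message carries the location."""


def _fail(loc: str, msg: str) -> None:
    raise AssessmentParseError(f"{loc}: {msg}")


def read_assessment(path: Union[str, Path], format: Optional[str] = None) -> list[Assessment]:
    """Read assessments from a JSON document or a CSV batch table.

    Format defaults from the file suffix.  Always returns a list (length 1
    for JSON documents).
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        return [read_assessment_json(path)]
    if fmt == "csv":
        return read_assessment_csv(path)
    raise AssessmentParseError(f"{path}: unknown format {fmt!r}")


def read_assessment_json(path: Union[str, Path]) -> Assessment:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        _fail(str(path), f"malformed JSON ({e})")
    if not isinstance(doc, dict):
        _fail(str(path), "document must be a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        _fail(str(path), f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})")
    body = doc.get("assessment")
    if not isinstance(body, dict):
        _fail(str(path), "missing 'assessment' object")
    extra = set(doc) - {"schema_version", "assessment"}
    if extra:
        _fail(str(path), f"unknown top-level fields {sorted(extra)}")
    try:
        return Assessment.model_validate(body)
    except ValidationError as e:
        _fail(str(path), _summarize(e))
    raise AssertionError("unreachable")


def _summarize(e: ValidationError) -> str:
    parts = [
        "/".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors()
    ]
    return "; ".join(parts)


def _cell(row: pd.Series, col: str) -> Optional[float]:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise AssessmentParseError(f"column {col!r}: not a number: {v!r}")


def _row_to_assessment(row: pd.Series, loc: str) -> Assessment:
    fields: dict = {}
    site = row.get("site_id")
    if site is None or (isinstance(site, float) and math.isnan(site)) or site == "":
        _fail(loc, "missing site_id")
    fields["site_id"] = str(site)
    date = row.get("assessed_at")
    if date is None or (isinstance(date, float) and math.isnan(date)) or date == "":
        _fail(loc, "missing assessed_at")
    fields["assessed_at"] = str(date)

    period = _cell(row, "period_days")
    denom = _cell(row, "rate_denominator") or 10_000
    if period is not None:
        fields["period_days"] = period

    def window(obs_col: str, base_col: str, pop_col: str) -> Optional[MortalityWindow]:
        obs, base, pop = _cell(row, obs_col), _cell(row, base_col), _cell(row, pop_col)
        if obs is None and base is None and pop is None:
            return None
        if obs is None or base is None or pop is None:
            _fail(loc, f"{obs_col}/{base_col}/{pop_col} must be given together")
        if period is None:
            _fail(loc, f"period_days is required with {obs_col}")
        return MortalityWindow(
            observed_rate=obs,
            baseline_rate=base,
            population_at_risk=pop,
            period_days=period,
            denominator=denom,
        )

    try:
        w = window("cmr_observed", "cmr_baseline", "population_at_risk")
        if w is not None:
            fields["mortality"] = w
        w5 = window("u5mr_observed", "u5mr_baseline", "under5_population")
        if w5 is not None:
            fields["under5_mortality"] = w5

        tested = _cell(row, "water_samples_tested")
        polluted = _cell(row, "water_samples_polluted")
        if (tested is None) != (polluted is None):
            _fail(loc, "water_samples_tested and water_samples_polluted must be given together")
        if tested is not None:
            fields["water_samples"] = WaterSampleSet(
                n_samples=int(tested), n_polluted=int(polluted)
            )

        for col in _INT_FIELDS:
            v = _cell(row, col)
            if v is not None:
                if v != int(v):
                    _fail(loc, f"column {col!r}: {v:g} is not an integer")
                fields[col] = int(v)
        for col in ("water_quantity_lpd", "water_polluted_pct"):
            v = _cell(row, col)
            if v is not None:
                fields[col] = v
        return Assessment.model_validate(fields)
    except (ValidationError, ValueError) as e:
        if isinstance(e, AssessmentParseError):
            raise
        msg = _summarize(e) if isinstance(e, ValidationError) else str(e)
        _fail(loc, msg)
    raise AssertionError("unreachable")


def read_assessment_csv(path: Union[str, Path]) -> list[Assessment]:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"site_id": str, "assessed_at": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        _fail(str(path), f"malformed CSV ({e})")
    unknown = set(df.columns) - _CSV_COLUMNS
    if unknown:
        _fail(str(path), f"unknown columns {sorted(unknown)}")
    if df.empty:
        _fail(str(path), "no assessments")
    return [
        _row_to_assessment(row, f"{path}, row {i + 2}")  # +2: header + 1-based
        for i, (_, row) in enumerate(df.iterrows())
    ]


# ---------------------------------------------------------------------------
# reports


def _result_to_json(r: PhissResult) -> str:
    return json.dumps(r.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"


def read_report_json(path: Union[str, Path]) -> PhissResult:
    return PhissResult.model_validate(json.loads(Path(path).read_text()))


def _fmt_raw(v: Optional[float]) -> str:
    if v is None:
        return "—"
    if v == int(v):
        return f"{int(v):,}"
    return f"{v:,.2f}"


def _result_to_markdown(r: PhissResult) -> str:
    lines = [
        f"# PHISS report — {r.site_id} ({r.assessed_at.isoformat()})",
        "",
        "| Parameter | Category | Raw value | Severity score | Max |",
        "|---|---|---:|---:|---:|",
    ]
    for ps in r.parameter_scores:
        score = "—" if ps.score is None else str(ps.score)
        lines.append(
            f"| {ps.parameter_id} | {ps.category.value} | {_fmt_raw(ps.raw_value)} "
            f"| {score} | {ps.max_score} |"
        )
    lines += ["", "## Category subtotals", ""]
    for cat in sorted(r.category_subtotals):
        sc, mx = r.category_subtotals[cat]
        lines.append(f"- {cat}: {sc} / {mx}")
    lines += [
        "",
        f"**Total: {r.total} / {r.total_max_possible}**",
        "",
        f"- answered maximum: {r.answered_max}",
        f"- completeness: {len([p for p in r.parameter_scores if p.present])}/12 "
        f"({100 * r.completeness:.1f}%)",
    ]
    if r.normalized_total is not None:
        lines.append(f"- normalized total (vs answered max): {r.normalized_total:.1f}")
    if r.mortality_period_days is not None:
        lines.append(f"- mortality window: {r.mortality_period_days:g} days")
    if r.under5_period_days is not None:
        lines.append(f"- under-5 mortality window: {r.under5_period_days:g} days")
    return "\n".join(lines) + "\n"


def _result_to_csv(r: PhissResult) -> str:
    rows = []
    for ps in r.parameter_scores:
        rows.append(
            {
                "record": "parameter",
                "key": ps.parameter_id,
                "category": ps.category.value,
                "raw_value": "" if ps.raw_value is None else f"{ps.raw_value:g}",
                "score": "" if ps.score is None else ps.score,
                "max_score": ps.max_score,
            }
        )
    for cat in sorted(r.category_subtotals):
        sc, mx = r.category_subtotals[cat]
        rows.append(
            {
                "record": "subtotal",
                "key": cat,
                "category": cat,
                "raw_value": "",
                "score": sc,
                "max_score": mx,
            }
        )
    rows.append(
        {
            "record": "total",
            "key": "total",
            "category": "",
            "raw_value": "",
            "score": r.total,
            "max_score": r.total_max_possible,
        }
    )
    df = pd.DataFrame(rows)
    return df.to_csv(index=False, lineterminator="\n")


def write_report(
    r: PhissResult,
    path: Union[str, Path, TextIO, None] = None,
    format: str = "json",
) -> str:
    """Render a result and write it to ``path`` (file, stream, or stdout).

    Returns the rendered text; output is byte-stable for a fixed result.
    """
    renderers = {"json": _result_to_json, "markdown": _result_to_markdown,
                 "md": _result_to_markdown, "csv": _result_to_csv}
    if format not in renderers:
        raise ValueError(f"unknown report format {format!r}")
    text = renderers[format](r)
    if path is None:
        sys.stdout.write(text)
    elif hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)
    return text


def write_assessment_json(a: Assessment, path: Union[str, Path]) -> None:
    """Write an assessment back out as a canonical JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "assessment": a.model_dump(mode="json", exclude_none=True),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
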