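"""Reading EMS patient-care charts and flattening them into sentence documents.

Charts follow a documented flat JSON dialect with NEMSIS-v3-style element
names (patient demographics, event times, one row per medication
administration, and a free-text narrative).  Structured fields are verbalized
through hand-written templates ("the patient weighs 12 kg") and the narrative
is split into sentences; the two streams are concatenated — templated
sentences first, narrative sentences in source order — into a single
:class:`SentenceDocument` that downstream extraction consumes.

The reader is intentionally forgiving: a malformed timestamp becomes a
per-field parse error retained on the chart (the engine later reports a
missing input with a traceable origin) rather than an ingestion failure.
Only a missing ``chart_id`` is fatal.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator

log = logging.getLogger(__name__)

__all__ = [
    "ChartError",
    "MedicationAdministration",
    "ClinicalChart",
    "Sentence",
    "SentenceDocument",
    "DEFAULT_TEMPLATES",
    "read_chart",
    "read_chart_file",
    "read_charts_csv",
    "templatize_structured",
    "tokenize_narrative",
    "assemble_document",
]


class ChartError(ValueError):
    """Fatal chart-level problem (e.g. missing chart_id)."""


def parse_timestamp(raw: Any) -> datetime:
    """Parse an ISO-8601 timestamp; naive times are taken as UTC."""
    if isinstance(raw, datetime):
        dt = raw
    elif isinstance(raw, str):
        dt = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    else:
        raise ValueError(f"not a timestamp: {raw!r}")
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


class MedicationAdministration(BaseModel):
    drug_name: str
    dose_value: float = Field(ge=0)
    dose_unit: str
    route: str = ""
    time: Optional[datetime] = None

    @field_validator("dose_unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        u = v.strip().lower()
        if u not in {"mg", "mcg"}:
            raise ValueError(f"dose unit must be mg or mcg, got {v!r}")
        return u


class ClinicalChart(BaseModel):
    """One EMS encounter: typed structured fields plus the verbatim narrative."""

    chart_id: str = Field(min_length=1)
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    unit_arrival_time: Optional[datetime] = None
    arrest_onset_time: Optional[datetime] = None
    administrations: list[MedicationAdministration] = Field(default_factory=list)
    narrative: str = ""
    field_errors: dict[str, str] = Field(default_factory=dict)

    @field_validator("weight_kg")
    @classmethod
    def _weight(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("weight, if present, must be positive")
        return v


@dataclass(frozen=True)
class Sentence:
    """One sentence with its provenance: a templated structured field, or a
    character span of the narrative."""

    text: str
    source: str            # "templated" | "narrative"
    field: Optional[str] = None          # templated only
    span: Optional[tuple[int, int]] = None  # narrative only


@dataclass(frozen=True)
class SentenceDocument:
    sentences: tuple[Sentence, ...]

    def __len__(self) -> int:
        return len(self.sentences)

    def texts(self) -> list[str]:
        return [s.text for s in self.sentences]


def _num(x: float) -> str:
    return f"{x:g}"


def _ts(dt: datetime) -> str:
    return dt.isoformat()


#: Default sentence templates for structured NEMSIS-style fields.  Keys are
#: chart attribute names; ``administration`` applies per medication row.
DEFAULT_TEMPLATES: dict[str, str] = {
    "age_years": "the patient is {age_years} years old",
    "weight_kg": "the patient weighs {weight_kg} kg",
    "unit_arrival_time": "the unit arrived on scene at {unit_arrival_time}",
    "arrest_onset_time": "cardiac arrest began at {arrest_onset_time}",
    "administration": "{drug_name} {dose_value} {dose_unit} was administered at {time}",
}


def read_chart(record: Mapping[str, Any]) -> ClinicalChart:
    """Convert one chart document (the flat JSON dialect) to a ClinicalChart.

    Per-field parse failures are retained in ``field_errors`` with the field
    left absent; downstream execution then reports a traceable missing input.
    """
    chart_id = record.get("chart_id")
    if not chart_id:
        raise ChartError("chart document is missing chart_id")

    errors: dict[str, str] = {}
    patient = record.get("patient", {}) or {}
    times = record.get("times", {}) or {}

    def opt_number(section: Mapping[str, Any], key: str, label: str) -> Optional[float]:
        raw = section.get(key)
        if raw is None:
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            errors[label] = f"unparseable number: {raw!r}"
            return None

    def opt_time(section: Mapping[str, Any], key: str, label: str) -> Optional[datetime]:
        raw = section.get(key)
        if raw is None:
            return None
        try:
            return parse_timestamp(raw)
        except ValueError:
            errors[label] = f"unparseable timestamp: {raw!r}"
            return None

    age = opt_number(patient, "age_years", "patient.age_years")
    weight = opt_number(patient, "weight_kg", "patient.weight_kg")
    if weight is not None and weight <= 0:
        errors["patient.weight_kg"] = f"non-positive weight: {weight!r}"
        weight = None
    arrival = opt_time(times, "unit_arrival", "times.unit_arrival")
    arrest = opt_time(times, "arrest_onset", "times.arrest_onset")

    admins: list[MedicationAdministration] = []
    for i, med in enumerate(record.get("medications", []) or []):
        label = f"medications[{i}]"
        try:
            t = med.get("time")
            admins.append(
                MedicationAdministration(
                    drug_name=str(med.get("name", "")).strip().lower(),
                    dose_value=float(med["dose"]),
                    dose_unit=str(med.get("unit", "mg")),
                    route=str(med.get("route", "")),
                    time=parse_timestamp(t) if t is not None else None,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            errors[label] = str(exc)

    return ClinicalChart(
        chart_id=str(chart_id),
        age_years=age,
        weight_kg=weight,
        unit_arrival_time=arrival,
        arrest_onset_time=arrest,
        administrations=admins,
        narrative=str(record.get("narrative", "") or ""),
        field_errors=errors,
    )


def read_chart_file(path: str | Path) -> list[ClinicalChart]:
    """Read one chart (JSON object) or a cohort (JSON list) from a file."""
    doc = json.loads(Path(path).read_text())
    records = doc if isinstance(doc, list) else [doc]
    return [read_chart(r) for r in records]


def read_charts_csv(charts_csv: str | Path, administrations_csv: str | Path) -> list[ClinicalChart]:
    """CSV dialect: one chart per row, one administration per row, joined on chart_id."""
    cdf = pd.read_csv(charts_csv, dtype={"chart_id": str})
    adf = pd.read_csv(administrations_csv, dtype={"chart_id": str})
    by_chart = dict(tuple(adf.groupby("chart_id"))) if len(adf) else {}
    charts = []
    for row in cdf.to_dict("records"):
        meds = []
        for m in by_chart.get(str(row["chart_id"]), pd.DataFrame()).to_dict("records"):
            meds.append({"name": m.get("name"), "dose": m.get("dose"),
                         "unit": m.get("unit"), "route": m.get("route", ""),
                         "time": m.get("time")})
        record = {
            "chart_id": row["chart_id"],
            "patient": {k: row.get(k) for k in ("age_years", "weight_kg") if pd.notna(row.get(k))},
            "times": {k2: row.get(k1) for k1, k2 in
                      (("unit_arrival", "unit_arrival"), ("arrest_onset", "arrest_onset"))
                      if isinstance(row.get(k1), str)},
            "medications": meds,
            "narrative": row.get("narrative", "") if isinstance(row.get("narrative"), str) else "",
        }
        charts.append(read_chart(record))
    return charts


def templatize_structured(
    chart: ClinicalChart,
    templates: Optional[Mapping[str, str]] = None,
) -> list[Sentence]:
    """One sentence per populated structured field; absent fields yield none.

    A template referencing a missing component is skipped with a warning
    rather than raising.
    """
    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    out: list[Sentence] = []

    scalar_values: dict[str, Any] = {}
    if chart.age_years is not None:
        scalar_values["age_years"] = _num(chart.age_years)
    if chart.weight_kg is not None:
        scalar_values["weight_kg"] = _num(chart.weight_kg)
    if chart.unit_arrival_time is not None:
        scalar_values["unit_arrival_time"] = _ts(chart.unit_arrival_time)
    if chart.arrest_onset_time is not None:
        scalar_values["arrest_onset_time"] = _ts(chart.arrest_onset_time)

    for field in ("age_years", "weight_kg", "unit_arrival_time", "arrest_onset_time"):
        if field not in scalar_values or field not in templates:
            continue
        try:
            out.append(Sentence(templates[field].format(**scalar_values), "templated", field=field))
        except (KeyError, IndexError) as exc:
            log.warning("template for %s references missing component: %s", field, exc)

    admin_tpl = templates.get("administration")
    if admin_tpl:
        for i, adm in enumerate(chart.administrations):
            if adm.time is None:
                log.warning("administration %d on chart %s lacks a time; templated without it",
                            i, chart.chart_id)
            try:
                out.append(Sentence(
                    admin_tpl.format(
                        drug_name=adm.drug_name,
                        dose_value=_num(adm.dose_value),
                        dose_unit=adm.dose_unit,
                        time=_ts(adm.time) if adm.time else "an undocumented time",
                    ),
                    "templated",
                    field=f"administration[{i}]",
                ))
            except (KeyError, IndexError) as exc:
                log.warning("administration template skipped: %s", exc)
    return out


# Trailing tokens after which a period does not end a sentence.
_ABBREVIATIONS = {
    "approx", "pt", "pts", "dr", "mr", "mrs", "ms", "vs", "etc", "no",
    "wt", "est", "resp", "hx", "tx",
    "e.g", "i.e", "i.v", "i.o", "b.p", "a.m", "p.m",
}

_BOUNDARY = re.compile(r"([.!?]+)(\s+)")


def tokenize_narrative(text: str) -> list[str]:
    """Split free text into sentences with a punctuation-rule tokenizer.

    Periods after common clinical abbreviations ("approx.", "pt.", "i.v.")
    do not end a sentence; decimal points never do (no whitespace follows).
    Whitespace is normalized within each sentence; empty input yields [].
    """
    return [s for s, _, _ in _tokenize_spans(text)]


def _tokenize_spans(text: str) -> list[tuple[str, int, int]]:
    """Sentences with their (start, end) character spans in the source text."""
    if not text or not text.strip():
        return []
    spans: list[tuple[str, int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        before = text[start:m.end(1)]
        last = re.findall(r"[\w./]+", before[:-len(m.group(1))] if m.group(1) else before)
        token = (last[-1].lower().rstrip(".") if last else "")
        if m.group(1) == "." and token in _ABBREVIATIONS:
            continue  # abbreviation, not a boundary
        raw = text[start:m.end(1)]
        if raw.strip():
            spans.append((" ".join(raw.split()), start, m.end(1)))
        start = m.end()
    tail = text[start:]
    if tail.strip():
        spans.append((" ".join(tail.split()), start, len(text)))
    return spans


def assemble_document(
    chart: ClinicalChart,
    templates: Optional[Mapping[str, str]] = None,
) -> SentenceDocument:
    """Templated sentences followed by narrative sentences, with provenance."""
    sentences = list(templatize_structured(chart, templates))
    for text, s, e in _tokenize_spans(chart.narrative):
        sentences.append(Sentence(text, "narrative", span=(s, e)))
    return SentenceDocument(tuple(sentences))
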