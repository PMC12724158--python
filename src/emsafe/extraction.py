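"""Zero-shot retrieval of ontology input values from a sentence document.

The extractor contract is deliberately narrow: a backend receives a prompt
embedding the full document plus a JSON-Schema-shaped output schema, and must
return schema-conformant JSON text.  Nothing else — no state between calls,
no temperature, no tool use.  Non-conformant output gets one retry, after
which every slot degrades to an explicit ``not_found`` abstention.

Abstention is a first-class outcome, not a failure: when the chart states
conflicting values for a fact (duplicate entries with different weights,
say), the extractor returns *no* value with reason ``conflicting_values``
rather than guessing, and the rule engine later reports a traceable missing
input.  This "refuse rather than fabricate" policy is what keeps the
downstream determinations auditable.

:class:`MockExtractor` is the bundled deterministic backend: it parses the
numbered sentences back out of the prompt and applies type-specific regular
expressions (quantities with units, ISO timestamps, drug-dose-time triples).
It is the offline test surface standing in for a hosted language model, and
honors the same contract through the same :func:`extract` code path.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Any, Mapping, Optional, Protocol, Sequence, Union

from .ingest import SentenceDocument, parse_timestamp
from .ontology import ConceptNode, Ontology
from .units import convert

__all__ = [
    "Abstention",
    "ExtractedValue",
    "AdministrationFact",
    "ExtractionResult",
    "ExtractionQuery",
    "Extractor",
    "ExtractorTransportError",
    "MockExtractor",
    "build_query",
    "build_prompt",
    "extract",
    "mock_extract",
    "ExtractionAudit",
    "audit_extraction",
]

EPI_NAMES = {"epinephrine", "epi", "adrenaline"}

#: Node ids realized through the administrations array slot rather than
#: scalar slots (per-administration dose/time facts).
ADMIN_NODES = {"administered_dose", "first_epi_time"}


@dataclass(frozen=True)
class Abstention:
    """Deliberate refusal to output a value."""

    reason: str  # "not_found" | "conflicting_values"

    def __post_init__(self) -> None:
        if self.reason not in ("not_found", "conflicting_values"):
            raise ValueError(f"invalid abstention reason {self.reason!r}")


@dataclass(frozen=True)
class ExtractedValue:
    value: Any
    unit: Optional[str] = None
    support: tuple[int, ...] = ()  # sentence indices


@dataclass(frozen=True)
class AdministrationFact:
    drug: str
    time: Optional[datetime]
    dose_mg: Optional[float]          # None when abstained
    abstain_reason: Optional[str] = None
    support: tuple[int, ...] = ()


@dataclass(frozen=True)
class ExtractionResult:
    """Per-node value or abstention, plus the extracted administration table."""

    values: dict[str, Union[ExtractedValue, Abstention]]
    administrations: tuple[AdministrationFact, ...] = ()

    def value_or_none(self, node_id: str) -> Any:
        v = self.values.get(node_id)
        return v.value if isinstance(v, ExtractedValue) else None


@dataclass(frozen=True)
class ExtractionQuery:
    nodes: tuple[ConceptNode, ...]
    document: SentenceDocument

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("nothing to extract: empty node list")
        bad = [n.node_id for n in self.nodes if n.kind != "input"]
        if bad:
            raise ValueError(f"only input nodes can be extracted, got {bad}")


class Extractor(Protocol):
    """Stateless text-in / structured-text-out backend contract."""

    def complete(self, prompt: str, schema: Mapping[str, Any]) -> str: ...


class ExtractorTransportError(RuntimeError):
    """Retriable backend/transport failure — distinct from abstention."""


def build_query(
    onto: Ontology,
    document: SentenceDocument,
    targets: Optional[Sequence[str]] = None,
) -> ExtractionQuery:
    """Query covering all input nodes (default) or those feeding ``targets``."""
    if targets is None:
        nodes = sorted(onto.input_nodes, key=lambda n: n.node_id)
    else:
        from .ontology import required_inputs

        wanted: set[str] = set()
        for t in targets:
            wanted |= required_inputs(onto, t)
        nodes = [onto.nodes[nid] for nid in sorted(wanted)]
    return ExtractionQuery(tuple(nodes), document)


def _scalar_slot_schema(node: ConceptNode) -> dict[str, Any]:
    vt = {"number": ["number", "null"],
          "quantity": ["number", "null"],
          "timestamp": ["string", "null"],
          "boolean": ["boolean", "null"],
          "categorical": ["string", "null"]}[node.value_type.type]
    return {
        "type": "object",
        "properties": {
            "status": {"enum": ["found", "not_found", "conflicting_values"]},
            "value": {"type": vt},
            "unit": {"type": ["string", "null"]},
            "support": {"type": "array", "items": {"type": "integer"}},
        },
        "required": ["status"],
    }


_ADMIN_SLOT_SCHEMA = {
    "type": "array",
    "items": {
        "type": "object",
        "properties": {
            "drug": {"type": "string"},
            "dose": {"type": ["number", "null"]},
            "unit": {"type": ["string", "null"]},
            "time": {"type": ["string", "null"]},
            "status": {"enum": ["found", "conflicting_values"]},
            "support": {"type": "array", "items": {"type": "integer"}},
        },
        "required": ["drug", "status"],
    },
}


def build_prompt(query: ExtractionQuery) -> tuple[str, dict[str, Any]]:
    """Render the dynamic prompt and its structured-output schema.

    The prompt embeds every sentence of the document (numbered, so support
    indices are meaningful) and, per requested node, its description and
    expected type.  The schema has one nullable slot per scalar node plus one
    ``administrations`` array slot when per-administration facts are queried.
    """
    scalar_nodes = [n for n in query.nodes if n.node_id not in ADMIN_NODES]
    want_admins = any(n.node_id in ADMIN_NODES for n in query.nodes)

    properties: dict[str, Any] = {n.node_id: _scalar_slot_schema(n) for n in scalar_nodes}
    if want_admins:
        properties["administrations"] = dict(_ADMIN_SLOT_SCHEMA)
    schema = {
        "type": "object",
        "properties": properties,
        "required": sorted(properties),
        "additionalProperties": False,
    }

    lines = [
        "You are reviewing an emergency medical services patient-care chart.",
        "Extract the requested facts from the numbered sentences below, using",
        "only information stated in the sentences. If a fact is not stated,",
        'use status "not_found"; if the sentences state conflicting values',
        'for the same fact, use status "conflicting_values" and no value —',
        "never guess. Report supporting sentence numbers in 'support'.",
        "",
        "Sentences:",
    ]
    for i, s in enumerate(query.document.sentences):
        lines.append(f"[{i}] {s.text}")
    lines.append("")
    lines.append("Facts to extract:")
    for n in scalar_nodes:
        t = n.value_type.type + (f", {n.value_type.unit}" if n.value_type.unit else "")
        hint = f" Hint: {n.extraction_hint}." if n.extraction_hint else ""
        lines.append(f"- {n.node_id} ({t}): {n.description}{hint}")
    if want_admins:
        lines.append(
            "- administrations (array): every documented medication"
            " administration with drug name, dose, dose unit, and time."
        )
    lines.append("")
    lines.append("Return a single JSON object conforming to this schema:")
    lines.append(json.dumps(schema, sort_keys=True))
    return "\n".join(lines), schema


def _validate_payload(data: Any, query: ExtractionQuery, schema: Mapping[str, Any]) -> None:
    """Hand-written structural validation of backend output against the schema."""
    if not isinstance(data, dict):
        raise ValueError("backend output is not a JSON object")
    for key in schema["required"]:
        if key not in data:
            raise ValueError(f"missing slot {key!r}")
    for key in data:
        if key not in schema["properties"]:
            raise ValueError(f"unexpected slot {key!r}")
    for node in query.nodes:
        if node.node_id in ADMIN_NODES:
            continue
        slot = data[node.node_id]
        if not isinstance(slot, dict) or slot.get("status") not in (
            "found", "not_found", "conflicting_values",
        ):
            raise ValueError(f"slot {node.node_id!r} malformed")
        if slot["status"] == "found":
            v = slot.get("value")
            kind = node.value_type.type
            if kind in ("number", "quantity") and not isinstance(v, (int, float)):
                raise ValueError(f"slot {node.node_id!r}: expected a number")
            if kind == "timestamp" and not isinstance(v, str):
                raise ValueError(f"slot {node.node_id!r}: expected an ISO timestamp string")
            if kind == "boolean" and not isinstance(v, bool):
                raise ValueError(f"slot {node.node_id!r}: expected a boolean")
            if kind == "categorical":
                if v not in (node.value_type.levels or []):
                    raise ValueError(f"slot {node.node_id!r}: {v!r} not a declared level")
    if "administrations" in data:
        if not isinstance(data["administrations"], list):
            raise ValueError("administrations slot must be an array")
        for entry in data["administrations"]:
            if not isinstance(entry, dict) or "drug" not in entry or entry.get("status") not in (
                "found", "conflicting_values",
            ):
                raise ValueError("malformed administration entry")


def _result_from_payload(data: Mapping[str, Any], query: ExtractionQuery) -> ExtractionResult:
    values: dict[str, Union[ExtractedValue, Abstention]] = {}
    for node in query.nodes:
        if node.node_id in ADMIN_NODES:
            continue
        slot = data[node.node_id]
        if slot["status"] != "found":
            values[node.node_id] = Abstention(slot["status"])
            continue
        val, unit = slot.get("value"), slot.get("unit")
        if node.value_type.type == "quantity" and unit and node.value_type.unit:
            val = convert(float(val), unit, node.value_type.unit)
            unit = node.value_type.unit
        elif node.value_type.type == "quantity":
            unit = node.value_type.unit
        if node.value_type.type == "timestamp":
            val = parse_timestamp(val)
        values[node.node_id] = ExtractedValue(val, unit, tuple(slot.get("support", ())))

    admins: list[AdministrationFact] = []
    for entry in data.get("administrations", []):
        t = parse_timestamp(entry["time"]) if entry.get("time") else None
        if entry["status"] == "conflicting_values":
            admins.append(AdministrationFact(entry["drug"], t, None,
                                             "conflicting_values", tuple(entry.get("support", ()))))
            continue
        dose = entry.get("dose")
        if dose is not None and entry.get("unit"):
            dose = convert(float(dose), entry["unit"], "mg")
        admins.append(AdministrationFact(entry["drug"], t,
                                         float(dose) if dose is not None else None,
                                         None if dose is not None else "not_found",
                                         tuple(entry.get("support", ()))))
    admins.sort(key=lambda a: (a.time is None, a.time))

    queried = {n.node_id for n in query.nodes}
    epi = [a for a in admins if a.drug.lower() in EPI_NAMES]
    if "first_epi_time" in queried:
        timed = [a for a in epi if a.time is not None]
        if timed:
            first = min(timed, key=lambda a: a.time)
            values["first_epi_time"] = ExtractedValue(first.time, None, first.support)
        else:
            values["first_epi_time"] = Abstention("not_found")
    if "administered_dose" in queried:
        doses = [a.dose_mg for a in epi if a.dose_mg is not None]
        if doses:
            support = tuple(sorted({i for a in epi for i in a.support}))
            values["administered_dose"] = ExtractedValue(doses, "mg", support)
        elif any(a.abstain_reason == "conflicting_values" for a in epi):
            values["administered_dose"] = Abstention("conflicting_values")
        else:
            values["administered_dose"] = Abstention("not_found")
    return ExtractionResult(values, tuple(admins))


def extract(backend: Extractor, query: ExtractionQuery, *, retries: int = 1) -> ExtractionResult:
    """Run one extraction call and parse/validate the structured output.

    Non-conformant backend output is retried once; if it still fails, every
    slot becomes an explicit ``not_found`` abstention (never a partial or
    guessed result).  Transport errors propagate as
    :class:`ExtractorTransportError` and are the caller's concern.
    """
    prompt, schema = build_prompt(query)
    last_error: Optional[Exception] = None
    for _ in range(retries + 1):
        raw = backend.complete(prompt, schema)
        try:
            data = json.loads(raw)
            _validate_payload(data, query, schema)
            return _result_from_payload(data, query)
        except (json.JSONDecodeError, ValueError) as exc:
            last_error = exc
    values = {n.node_id: Abstention("not_found") for n in query.nodes}
    return ExtractionResult(values, ())


# --------------------------------------------------------------------------
# Deterministic mock backend
# --------------------------------------------------------------------------

_ISO = r"\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(?:\.\d+)?(?:Z|[+-]\d{2}:\d{2})?"

_MATCHERS: dict[str, tuple[str, str, str]] = {
    # slot -> (context regex, value regex, kind)
    "patient_weight": (r"(?i)\bweigh(?:s|t|ed)?\b|\bwt\b",
                       r"(?i)(\d+(?:\.\d+)?)\s*(kg|kilograms?)\b", "weight"),
    "patient_age": (r"(?i)\bage\b|\bold\b|\byear", r"(?i)(\d+(?:\.\d+)?)\s*(?:years?|yo|y/o)\b", "age"),
    "ems_arrival_time": (r"(?i)arriv", rf"({_ISO})", "time"),
    "arrest_onset_time": (r"(?i)arrest", rf"({_ISO})", "time"),
}

_ADMIN_RE = re.compile(
    rf"(?i)\b(epinephrine|epi|adrenaline)\b[^0-9]*?(\d+(?:\.\d+)?)\s*(mg|mcg)\b.*?({_ISO})"
)

_PROMPT_SENTENCE_RE = re.compile(r"^\[(\d+)\]\s(.*)$", re.MULTILINE)


class MockExtractor:
    """Pattern-based offline backend honoring the Extractor contract.

    Scans the numbered sentences embedded in the prompt with type-specific
    patterns.  Per slot: zero matches → ``not_found``; more than one distinct
    normalized value → ``conflicting_values``; exactly one → the value with
    sentence-level provenance.  Values are normalized (units converted,
    ``1 mg`` == ``1.0 mg``) before the conflict test, so identical mentions
    never count as conflicts.  Deterministic: same document, same output.
    """

    def complete(self, prompt: str, schema: Mapping[str, Any]) -> str:
        sentences = [(int(m.group(1)), m.group(2)) for m in _PROMPT_SENTENCE_RE.finditer(prompt)]
        out: dict[str, Any] = {}
        for slot in schema["properties"]:
            if slot == "administrations":
                out[slot] = self._administrations(sentences)
            else:
                out[slot] = self._scalar(slot, sentences)
        return json.dumps(out)

    def _scalar(self, slot: str, sentences: list[tuple[int, str]]) -> dict[str, Any]:
        if slot not in _MATCHERS:
            return {"status": "not_found"}
        ctx_re, val_re, kind = _MATCHERS[slot]
        found: dict[Any, list[int]] = {}
        raw_by_key: dict[Any, Any] = {}
        for idx, text in sentences:
            if not re.search(ctx_re, text):
                continue
            for m in re.finditer(val_re, text):
                if kind == "weight":
                    val = convert(float(m.group(1)), m.group(2), "kg")
                    key = round(val, 6)
                elif kind == "age":
                    val = float(m.group(1))
                    key = round(val, 6)
                else:  # time
                    val = parse_timestamp(m.group(1)).isoformat()
                    key = val
                found.setdefault(key, []).append(idx)
                raw_by_key[key] = val
        if not found:
            return {"status": "not_found"}
        if len(found) > 1:
            return {"status": "conflicting_values",
                    "support": sorted({i for idxs in found.values() for i in idxs})}
        key, idxs = next(iter(found.items()))
        val = raw_by_key[key]
        unit = {"weight": "kg", "age": None, "time": None}[kind]
        return {"status": "found", "value": val, "unit": unit, "support": sorted(set(idxs))}

    def _administrations(self, sentences: list[tuple[int, str]]) -> list[dict[str, Any]]:
        # mentions grouped by time; distinct doses at one time = conflict
        by_time: dict[str, dict[float, list[int]]] = {}
        for idx, text in sentences:
            for m in _ADMIN_RE.finditer(text):
                dose_mg = round(convert(float(m.group(2)), m.group(3), "mg"), 9)
                t = parse_timestamp(m.group(4)).isoformat()
                by_time.setdefault(t, {}).setdefault(dose_mg, []).append(idx)
        entries = []
        for t in sorted(by_time):
            doses = by_time[t]
            support = sorted({i for idxs in doses.values() for i in idxs})
            if len(doses) > 1:
                entries.append({"drug": "epinephrine", "dose": None, "unit": None,
                                "time": t, "status": "conflicting_values", "support": support})
            else:
                dose = next(iter(doses))
                entries.append({"drug": "epinephrine", "dose": dose, "unit": "mg",
                                "time": t, "status": "found", "support": support})
        return entries


def mock_extract(query: ExtractionQuery) -> ExtractionResult:
    """Convenience: run the bundled deterministic backend on ``query``."""
    return extract(MockExtractor(), query)


# --------------------------------------------------------------------------
# Extraction audit (error taxonomy)
# --------------------------------------------------------------------------

_AUDIT_SCALARS = ("patient_age", "patient_weight", "ems_arrival_time", "arrest_onset_time")


@dataclass
class ExtractionAudit:
    """Counts of empty-field errors (abstentions where the gold chart has a
    value), incorrect-value errors, and correct extractions, per variable."""

    per_variable: dict[str, dict[str, int]]
    n_charts: int
    charts_with_failures: int

    @property
    def failure_rate(self) -> float:
        return self.charts_with_failures / self.n_charts if self.n_charts else 0.0

    def totals(self) -> dict[str, int]:
        out = {"correct": 0, "empty_field_errors": 0, "incorrect_value_errors": 0}
        for counts in self.per_variable.values():
            for k in out:
                out[k] += counts[k]
        return out


def _values_match(var: str, got: Any, want: Any) -> bool:
    if var.endswith("_time"):
        return parse_timestamp(got) == parse_timestamp(want)
    return abs(float(got) - float(want)) <= 1e-6


def audit_extraction(
    results: Mapping[str, ExtractionResult],
    truth: Mapping[str, Mapping[str, Any]],
) -> ExtractionAudit:
    """Score extraction output against gold field values, chart by chart."""
    if set(results) != set(truth):
        raise ValueError("results and truth cover different chart ids")
    variables = _AUDIT_SCALARS + ("epi_administrations",)
    per_var = {v: {"correct": 0, "empty_field_errors": 0, "incorrect_value_errors": 0}
               for v in variables}
    failed_charts = 0
    for cid in sorted(results):
        res, gold = results[cid], truth[cid]
        chart_failed = False
        for var in _AUDIT_SCALARS:
            got = res.values.get(var)
            want = gold.get(var)
            if want is None:
                bucket = "correct" if not isinstance(got, ExtractedValue) else "incorrect_value_errors"
            elif isinstance(got, ExtractedValue):
                bucket = ("correct" if _values_match(var, got.value, want)
                          else "incorrect_value_errors")
            else:
                bucket = "empty_field_errors"
            per_var[var][bucket] += 1
            chart_failed |= bucket != "correct"

        want_admins = {(round(float(d), 6), parse_timestamp(t).isoformat())
                       for d, t in gold.get("epi_administrations", [])}
        got_admins = set()
        abstained = False
        for a in res.administrations:
            if a.dose_mg is None or a.time is None:
                abstained = True
            else:
                got_admins.add((round(a.dose_mg, 6), a.time.isoformat()))
        if abstained and want_admins:
            bucket = "empty_field_errors"
        elif got_admins == want_admins:
            bucket = "correct"
        else:
            bucket = "incorrect_value_errors"
        per_var["epi_administrations"][bucket] += 1
        chart_failed |= bucket != "correct"
        failed_charts += chart_failed
    return ExtractionAudit(per_var, len(results), failed_charts)
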