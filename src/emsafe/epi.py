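"""Epinephrine adverse-safety-event computations.

Clinical background: PALS indicates epinephrine at 0.01 mg per kg of body
weight in pediatric pulseless cardiac arrest.  Three error categories are
classified against weight-based thresholds:

======== ======================================= ==========================
category mild                                     severe
======== ======================================= ==========================
overdose dose >= 2x recommended                   dose >= 10x recommended
underdose dose <= 80% of recommended              dose <= 50% of recommended
delay    first dose >= 5 min after BOTH EMS       first dose >= 10 min after
         arrival and arrest onset                 both clocks
======== ======================================= ==========================

Severe thresholds nest inside mild ones, so every severe case also meets the
mild criterion.  Boundaries are inclusive and evaluated with a 1e-9 relative
tolerance: a 10x decimal-shift error whose ratio computes to
9.999999999... must still classify as severe.

The module exposes two faces.  The plain functions here
(:func:`recommended_dose`, :func:`classify_overdose`, ...) are straight-line
reference computations with no graph machinery.  :func:`determine_chart`
runs the same logic *through* the ontology and rule engine — per
administration for dosing, on the first epinephrine dose for delay — and
rolls severities up to the chart level, carrying execution traces and
propagated errors along for audit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Any, Mapping, Optional, Union

from .engine import ExecutionTrace, RuleRegistry, TraceError, bundled_registry, execute
from .extraction import Abstention, ExtractedValue, ExtractionResult, EPI_NAMES
from .ontology import Ontology, bundled_ontology

log = logging.getLogger(__name__)

__all__ = [
    "RECOMMENDED_MG_PER_KG",
    "SEVERITIES",
    "CATEGORIES",
    "recommended_dose",
    "dose_ratio",
    "classify_overdose",
    "classify_underdose",
    "delay_minutes",
    "classify_delay",
    "ASEDetermination",
    "CategoryResult",
    "ChartDetermination",
    "determine_chart",
]

RECOMMENDED_MG_PER_KG = 0.01

OVERDOSE_SEVERE_RATIO = 10.0
OVERDOSE_MILD_RATIO = 2.0
UNDERDOSE_SEVERE_RATIO = 0.5
UNDERDOSE_MILD_RATIO = 0.8
DELAY_SEVERE_MIN = 10.0
DELAY_MILD_MIN = 5.0

_REL_TOL = 1e-9

SEVERITIES = ("none", "mild", "severe")
CATEGORIES = ("overdose", "underdose", "delay")
_RANK = {s: i for i, s in enumerate(SEVERITIES)}


def recommended_dose(weight_kg: float) -> float:
    """Recommended epinephrine dose in mg: 0.01 mg/kg."""
    if weight_kg is None or weight_kg <= 0:
        raise ValueError("weight must be positive (kg)")
    return RECOMMENDED_MG_PER_KG * weight_kg


def dose_ratio(administered_mg: float, recommended_mg: float) -> float:
    """Administered / recommended, dimensionless."""
    if recommended_mg <= 0:
        raise ValueError("recommended dose must be positive (mg)")
    if administered_mg < 0:
        raise ValueError("administered dose must be non-negative (mg)")
    return administered_mg / recommended_mg


def classify_overdose(ratio: float) -> str:
    """severe at ratio >= 10, mild at >= 2, inclusive boundaries."""
    if ratio < 0:
        raise ValueError("dose ratio must be non-negative")
    if ratio >= OVERDOSE_SEVERE_RATIO * (1.0 - _REL_TOL):
        return "severe"
    if ratio >= OVERDOSE_MILD_RATIO * (1.0 - _REL_TOL):
        return "mild"
    return "none"


def classify_underdose(ratio: float) -> str:
    """severe at ratio <= 0.5, mild at <= 0.8, inclusive boundaries.

    A zero ratio means no drug was given — non-administration, a different
    event category — and is rejected.
    """
    if ratio <= 0:
        raise ValueError("a zero dose is non-administration, not an underdose")
    if ratio <= UNDERDOSE_SEVERE_RATIO * (1.0 + _REL_TOL):
        return "severe"
    if ratio <= UNDERDOSE_MILD_RATIO * (1.0 + _REL_TOL):
        return "mild"
    return "none"


def delay_minutes(
    first_epi_time: datetime,
    arrival_time: datetime,
    arrest_time: Optional[datetime] = None,
) -> tuple[float, Optional[float]]:
    """Elapsed minutes from arrival (and arrest onset, when known) to the
    first epinephrine dose.  A dose documented before arrival or before
    arrest onset is a data-quality error and raises."""
    from_arrival = (first_epi_time - arrival_time).total_seconds() / 60.0
    if from_arrival < 0:
        raise ValueError("first epinephrine dose precedes EMS arrival")
    from_arrest: Optional[float] = None
    if arrest_time is not None:
        from_arrest = (first_epi_time - arrest_time).total_seconds() / 60.0
        if from_arrest < 0:
            raise ValueError("first epinephrine dose precedes arrest onset")
    return from_arrival, from_arrest


def classify_delay(
    from_arrival: float,
    from_arrest: Optional[float] = None,
    *,
    policy: str = "strict",
) -> str:
    """Delay severity under AND-semantics over the two clocks.

    Both elapsed times must reach the threshold, i.e. the *minimum* of the
    two clocks is thresholded: severe at >= 10 min, mild at >= 5 min.  When
    arrest-onset time is unknown, the default ``strict`` policy refuses to
    classify (raises; in the engine this surfaces as a traceable missing
    input), while ``arrival_only`` classifies on the arrival clock alone.
    """
    if from_arrest is None:
        if policy == "arrival_only":
            effective = from_arrival
        elif policy == "strict":
            raise ValueError("arrest-onset time unknown; strict policy refuses to classify")
        else:
            raise ValueError(f"unknown delay policy {policy!r}")
    else:
        effective = min(from_arrival, from_arrest)
    if effective >= DELAY_SEVERE_MIN - 1e-9:
        return "severe"
    if effective >= DELAY_MILD_MIN - 1e-9:
        return "mild"
    return "none"


# ---------------------------------------------------------------------------
# Chart-level determination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASEDetermination:
    """One administration-level (or first-dose, for delay) determination."""

    category: str
    severity: str
    evidence: dict[str, Any]
    administration_index: Optional[int] = None


@dataclass
class CategoryResult:
    """Chart-level outcome for one category: worst severity across
    administrations, or a propagated error / skip reason when nothing could
    be classified."""

    severity: Optional[str] = None
    error: Optional[TraceError] = None
    evidence: dict[str, Any] = field(default_factory=dict)
    administration_index: Optional[int] = None
    skipped: Optional[str] = None


@dataclass
class ChartDetermination:
    chart_id: str
    categories: dict[str, CategoryResult]
    per_administration: list[ASEDetermination] = field(default_factory=list)
    traces: list[ExecutionTrace] = field(default_factory=list)

    def severity(self, category: str) -> Optional[str]:
        return self.categories[category].severity

    def to_dict(self, include_traces: bool = False) -> dict[str, Any]:
        def render(v: Any) -> Any:
            return v.isoformat() if isinstance(v, datetime) else v

        cats = {}
        for cat, res in self.categories.items():
            cats[cat] = {
                "severity": res.severity,
                "error": ({"kind": res.error.kind, "origin": res.error.origin,
                           "detail": res.error.detail} if res.error else None),
                "evidence": {k: render(v) for k, v in res.evidence.items()},
                "administration_index": res.administration_index,
                "skipped": res.skipped,
            }
        doc: dict[str, Any] = {"chart_id": self.chart_id, "categories": cats}
        if include_traces:
            doc["traces"] = [t.to_dict() for t in self.traces]
        return doc


def _worse(a: Optional[str], b: Optional[str]) -> Optional[str]:
    if a is None:
        return b
    if b is None:
        return a
    return a if _RANK[a] >= _RANK[b] else b


def determine_chart(
    chart_id: str,
    extraction: ExtractionResult,
    *,
    ontology: Optional[Ontology] = None,
    registry: Optional[RuleRegistry] = None,
    delay_policy: str = "strict",
) -> ChartDetermination:
    """Classify all three categories for one chart from its extracted facts.

    Overdose/underdose run once per extracted epinephrine administration and
    roll up to the worst severity; delay runs once on the first dose.  A
    chart documenting no epinephrine administration is not evaluated at all
    (failure-to-administer is a different event category).  Abstained or
    missing inputs surface as propagated errors with a traceable origin —
    never as fabricated severities.
    """
    onto = ontology or bundled_ontology()
    reg = registry or bundled_registry()
    cats = {c: CategoryResult() for c in CATEGORIES}
    det = ChartDetermination(chart_id, cats)

    epi_admins = [a for a in extraction.administrations if a.drug.lower() in EPI_NAMES]
    if not epi_admins:
        for c in CATEGORIES:
            cats[c].skipped = "no epinephrine administration documented"
        log.info("chart %s: no epinephrine administrations; not evaluated", chart_id)
        return det

    weight_raw = extraction.values.get("patient_weight", Abstention("not_found"))

    # --- dosing categories, once per administration -----------------------
    for i, adm in enumerate(epi_admins):
        dose_raw: Union[tuple, Abstention]
        if adm.dose_mg is None:
            dose_raw = Abstention(adm.abstain_reason or "not_found")
        else:
            dose_raw = (adm.dose_mg, "mg")
        inputs = {"patient_weight": _as_raw(weight_raw), "administered_dose": _as_raw(dose_raw)}

        trace = execute(onto, inputs, "overdose_ase", reg)
        det.traces.append(trace)
        _fold_dosing(det, "overdose", i, trace)

        if adm.dose_mg == 0:
            continue  # zero dose: non-administration, underdose not evaluated
        trace = execute(onto, inputs, "underdose_ase", reg)
        det.traces.append(trace)
        _fold_dosing(det, "underdose", i, trace)

    if all(a.dose_mg == 0 for a in epi_admins) and cats["underdose"].severity is None \
            and cats["underdose"].error is None:
        cats["underdose"].skipped = "only zero-dose records; treated as non-administration"

    # --- delay, on the first administration --------------------------------
    first_raw = extraction.values.get("first_epi_time", Abstention("not_found"))
    arrival_raw = extraction.values.get("ems_arrival_time", Abstention("not_found"))
    arrest_raw = extraction.values.get("arrest_onset_time", Abstention("not_found"))
    evidence_flags: dict[str, Any] = {}
    if delay_policy == "arrival_only" and isinstance(arrest_raw, (Abstention, type(None))):
        # Classify on the arrival clock alone: with arrest onset pinned to
        # arrival, min(from_arrival, from_arrest) reduces to from_arrival.
        arrest_raw = arrival_raw
        evidence_flags["delay_policy"] = "arrival_only (arrest clock imputed from arrival)"
    inputs = {
        "first_epi_time": _as_raw(first_raw),
        "ems_arrival_time": _as_raw(arrival_raw),
        "arrest_onset_time": _as_raw(arrest_raw),
    }
    trace = execute(onto, inputs, "delay_ase", reg)
    det.traces.append(trace)
    res = cats["delay"]
    if trace.outcome.ok:
        res.severity = trace.outcome.value
        res.administration_index = 0
        res.evidence = {
            "delay_from_arrival_min": trace.value_of("delay_from_arrival"),
            "delay_from_arrest_min": trace.value_of("delay_from_arrest"),
            "effective_delay_min": min(trace.value_of("delay_from_arrival"),
                                       trace.value_of("delay_from_arrest")),
            **evidence_flags,
        }
        det.per_administration.append(ASEDetermination("delay", res.severity, res.evidence, 0))
    else:
        res.error = trace.outcome.error
    return det


def _as_raw(v: Any) -> Any:
    if isinstance(v, ExtractedValue):
        return (v.value, v.unit) if v.unit is not None else v.value
    return v


def _fold_dosing(det: ChartDetermination, category: str, index: int, trace: ExecutionTrace) -> None:
    res = det.categories[category]
    out = trace.outcome
    if out.ok:
        evidence = {
            "administered_dose_mg": trace.value_of("administered_dose"),
            "recommended_dose_mg": trace.value_of("recommended_dose"),
            "dose_ratio": trace.value_of("dose_ratio"),
        }
        det.per_administration.append(ASEDetermination(category, out.value, evidence, index))
        worst = _worse(res.severity, out.value)
        if worst != res.severity or res.severity is None:
            res.severity = worst
            if worst == out.value:
                res.evidence = evidence
                res.administration_index = index
    else:
        if res.error is None:
            res.error = out.error
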