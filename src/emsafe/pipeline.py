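"""End-to-end chart review: ingest -> extract -> execute -> determine.

One extraction call per chart covers all the ontology's input nodes; the
three output determinations then run over the extracted facts through the
rule engine.  The backend defaults to the offline deterministic
:class:`~emsafe.extraction.MockExtractor` — an external language-model
endpoint is only ever contacted when explicitly passed in.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd

from .engine import RuleRegistry, bundled_registry
from .epi import ChartDetermination, determine_chart
from .extraction import Extractor, MockExtractor, build_query, extract
from .ingest import ClinicalChart, assemble_document
from .ontology import Ontology, bundled_ontology

__all__ = ["review_chart", "review_charts", "determinations_frame"]


def review_chart(
    chart: ClinicalChart,
    *,
    ontology: Optional[Ontology] = None,
    registry: Optional[RuleRegistry] = None,
    backend: Optional[Extractor] = None,
    templates: Optional[Mapping[str, str]] = None,
    delay_policy: str = "strict",
) -> ChartDetermination:
    """Run the full pipeline on one chart and return its determination."""
    onto = ontology or bundled_ontology()
    reg = registry or bundled_registry()
    document = assemble_document(chart, templates)
    query = build_query(onto, document)
    result = extract(backend or MockExtractor(), query)
    return determine_chart(chart.chart_id, result, ontology=onto, registry=reg,
                           delay_policy=delay_policy)


def review_charts(charts: Iterable[ClinicalChart], **kwargs) -> list[ChartDetermination]:
    """Review a cohort; per-chart problems become traceable errors in the
    determinations, never exceptions."""
    onto = kwargs.pop("ontology", None) or bundled_ontology()
    reg = kwargs.pop("registry", None) or bundled_registry()
    return [review_chart(c, ontology=onto, registry=reg, **kwargs) for c in charts]


def determinations_frame(dets: Iterable[ChartDetermination]) -> pd.DataFrame:
    """Flat audit table: one row per chart and category."""
    rows = []
    for det in dets:
        for cat, res in det.categories.items():
            rows.append({
                "chart_id": det.chart_id,
                "category": cat,
                "severity": res.severity,
                "error_kind": res.error.kind if res.error else None,
                "error_origin": res.error.origin if res.error else None,
                "skipped": res.skipped,
                **{f"evidence_{k}": v for k, v in res.evidence.items()},
            })
    return pd.DataFrame(rows)
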