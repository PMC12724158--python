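"""Synthetic pediatric OHCA chart cohorts with known ground truth.

No chart dataset ships with this package, so every stage is exercised on
generated cohorts: NEMSIS-dialect charts of pediatric out-of-hospital
cardiac arrest encounters, each with one or more epinephrine
administrations, a free-text narrative, and a gold record holding the true
field values and the true per-category severity labels.

Realism knobs model the documentation pathologies the error taxonomy cares
about: ``conflict_rate`` injects a conflicting duplicate value (a second,
different weight stated in the narrative); ``decimal_shift_rate`` records a
correct dose shifted one decimal place (x10 -> exactly a 10x overdose,
/10 -> a 50%-threshold-crossing underdose); ``narrative_rate`` moves facts
out of structured fields so they appear only as narrative paraphrases;
``rounding_jitter`` perturbs recorded doses by a small relative amount.

Gold labels are always derived from the *recorded* facts with inline
threshold arithmetic — this module shares no classification code with the
ontology rules or the reference functions, so end-to-end label recovery is
a genuine cross-implementation check, not a tautology.

Weight is sampled from age-banded pediatric ranges (roughly 50th-percentile
growth-curve spans); ages below 1 year are not modeled.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ingest import ClinicalChart, read_chart

__all__ = [
    "NoiseConfig",
    "CohortConfig",
    "GoldRecord",
    "generate_cohort",
    "inject_decimal_shift",
    "write_cohort",
]

# Generator-side thresholds, deliberately duplicated from the clinical rules
# (shared code here would make label-recovery tests circular).
_G_OVER_SEVERE, _G_OVER_MILD = 10.0, 2.0
_G_UNDER_SEVERE, _G_UNDER_MILD = 0.5, 0.8
_G_DELAY_SEVERE, _G_DELAY_MILD = 10.0, 5.0
_G_TOL = 1e-9

#: (age_lo, age_hi, (weight_lo_kg, weight_hi_kg)) pediatric bands.
AGE_WEIGHT_BANDS: tuple[tuple[int, int, tuple[float, float]], ...] = (
    (1, 3, (9.0, 15.0)),
    (4, 6, (14.0, 22.0)),
    (7, 10, (20.0, 36.0)),
    (11, 14, (34.0, 55.0)),
)

_BASE_DAY = datetime(2026, 3, 15, 8, 0, 0, tzinfo=timezone.utc)

_FLAVOR_POOL = (
    "Crew responded to a report of a collapsed child.",
    "Pt found pulseless and apneic.",
    "Bystander CPR in progress on arrival.",
    "High-quality compressions continued throughout transport.",
)
_WEIGHT_POOL = (
    "The patient weighs {w} kg.",
    "Pt weight approx. {w} kg.",
    "Weight: {w} kg.",
    "Estimated weight {w} kg per length-based tape.",
)
_AGE_POOL = (
    "The patient is {a} years old.",
    "Pt is a {a} year old.",
    "Age: {a} years.",
)
_ARRIVAL_POOL = (
    "EMS arrived on scene at {t}.",
    "Unit arrival time {t}.",
    "Crew arrived at {t}.",
)
_ARREST_POOL = (
    "Cardiac arrest began at {t}.",
    "Witnessed arrest at approx. {t}.",
    "Onset of cardiac arrest at {t}.",
)
_ADMIN_POOL = (
    "Epinephrine {d} mg administered at {t}.",
    "Gave epinephrine {d} mg IV at {t}.",
    "Epi {d} mg given at {t}.",
)


class NoiseConfig(BaseModel):
    """Documentation-noise probabilities, all in [0, 1]."""

    conflict_rate: float = Field(default=0.03, ge=0, le=1)
    conflict_field: str = "patient_weight"  # or "administered_dose"
    decimal_shift_rate: float = Field(default=0.05, ge=0, le=1)
    narrative_rate: float = Field(default=0.3, ge=0, le=1)
    rounding_jitter: float = Field(default=0.02, ge=0, le=0.03)

    @model_validator(mode="after")
    def _check(self) -> "NoiseConfig":
        if self.conflict_field not in ("patient_weight", "administered_dose"):
            raise ValueError("conflict_field must be patient_weight or administered_dose")
        return self


class CohortConfig(BaseModel):
    n_charts: int = Field(ge=1)
    seed: int  # mandatory: cohorts must be reproducible
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {"overdose": 0.1, "underdose": 0.1, "delay": 0.1}
    )
    severe_fraction: float = Field(default=0.5, ge=0, le=1)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for cat, p in self.prevalence.items():
            if cat not in ("overdose", "underdose", "delay"):
                raise ValueError(f"unknown category {cat!r} in prevalence")
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {cat} must be in [0,1]")
        return self

    @classmethod
    def noise_free(cls, n_charts: int, seed: int, **kw: Any) -> "CohortConfig":
        """Convenience: all noise channels off."""
        return cls(n_charts=n_charts, seed=seed,
                   noise=NoiseConfig(conflict_rate=0, decimal_shift_rate=0,
                                     narrative_rate=0, rounding_jitter=0), **kw)


@dataclass
class GoldRecord:
    """Field-level truth plus per-category severity labels for one chart."""

    chart_id: str
    labels: dict[str, str]
    age_years: int = 0
    weight_kg: float = 0.0
    unit_arrival: Optional[datetime] = None
    arrest_onset: Optional[datetime] = None
    administrations: list[tuple[float, datetime]] = field(default_factory=list)
    conflict_fields: list[str] = field(default_factory=list)
    decimal_shift: Optional[str] = None  # "up" | "down" | None

    def truth_fields(self) -> dict[str, Any]:
        """Gold values keyed by ontology input node, for extraction audits."""
        return {
            "patient_age": self.age_years,
            "patient_weight": self.weight_kg,
            "ems_arrival_time": self.unit_arrival.isoformat(),
            "arrest_onset_time": self.arrest_onset.isoformat(),
            "epi_administrations": [(d, t.isoformat()) for d, t in self.administrations],
        }


def inject_decimal_shift(dose_mg: float, direction: str) -> float:
    """Record a dose with a one-decimal-place transcription error.

    ``up`` multiplies by 10 (a correct dose becomes an exactly-10x severe
    overdose); ``down`` divides by 10 (ratio 0.1, a severe underdose).
    """
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if direction == "up":
        return dose_mg * 10.0
    if direction == "down":
        return dose_mg / 10.0
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def _gold_dosing(doses: list[float], weight_kg: float) -> tuple[str, str]:
    """Worst overdose/underdose labels from recorded doses (inline arithmetic)."""
    rank = {"none": 0, "mild": 1, "severe": 2}
    over, under = "none", "none"
    rec = 0.01 * weight_kg
    for dose in doses:
        ratio = dose / rec
        if ratio >= _G_OVER_SEVERE * (1 - _G_TOL):
            o = "severe"
        elif ratio >= _G_OVER_MILD * (1 - _G_TOL):
            o = "mild"
        else:
            o = "none"
        if 0 < ratio <= _G_UNDER_SEVERE * (1 + _G_TOL):
            u = "severe"
        elif 0 < ratio <= _G_UNDER_MILD * (1 + _G_TOL):
            u = "mild"
        else:
            u = "none"
        over = over if rank[over] >= rank[o] else o
        under = under if rank[under] >= rank[u] else u
    return over, under


def _gold_delay(first: datetime, arrival: datetime, arrest: datetime) -> str:
    eff = min((first - arrival).total_seconds(), (first - arrest).total_seconds()) / 60.0
    if eff >= _G_DELAY_SEVERE - _G_TOL:
        return "severe"
    if eff >= _G_DELAY_MILD - _G_TOL:
        return "mild"
    return "none"


def _sample_severity(rng: np.random.Generator, p_event: float, severe_fraction: float) -> str:
    if rng.random() >= p_event:
        return "none"
    return "severe" if rng.random() < severe_fraction else "mild"


def _pick(rng: np.random.Generator, pool: tuple[str, ...]) -> str:
    return pool[int(rng.integers(0, len(pool)))]


def generate_cohort(config: CohortConfig) -> tuple[list[ClinicalChart], list[GoldRecord]]:
    """Generate a cohort of charts with gold labels, deterministically.

    Every chart documents at least one epinephrine administration (the
    cohort emulates epinephrine-treated arrests; failure-to-administer is
    out of scope), and its gold labels are recomputed from the *recorded*
    facts, so label and chart can never disagree by construction.
    """
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    charts: list[ClinicalChart] = []
    gold: list[GoldRecord] = []

    for i in range(config.n_charts):
        chart_id = f"C{i:05d}"
        lo, hi, (wlo, whi) = AGE_WEIGHT_BANDS[int(rng.integers(0, len(AGE_WEIGHT_BANDS)))]
        age = int(rng.integers(lo, hi + 1))
        weight = round(float(rng.uniform(wlo, whi)), 1)
        rec = 0.01 * weight

        arrival = _BASE_DAY + timedelta(minutes=int(rng.integers(0, 540)))
        arrest = arrival - timedelta(seconds=int(rng.integers(0, 300)))

        sampled = {
            cat: _sample_severity(rng, config.prevalence.get(cat, 0.0), config.severe_fraction)
            for cat in ("overdose", "underdose", "delay")
        }

        # Delay target drives the first administration time.  Arrest precedes
        # arrival here, so the arrival clock is the binding (minimum) one.
        delay_band = {"none": (1.0, 4.4), "mild": (5.2, 9.4), "severe": (10.3, 14.5)}
        d_lo, d_hi = delay_band[sampled["delay"]]
        first_time = arrival + timedelta(seconds=round(float(rng.uniform(d_lo, d_hi)) * 60))

        # Dose ratios realizing the sampled dosing labels, with safety margins
        # so jitter and rounding cannot cross a threshold.
        ratios: list[float] = []
        if sampled["overdose"] == "severe":
            ratios.append(float(rng.uniform(10.5, 11.5)))
        elif sampled["overdose"] == "mild":
            ratios.append(float(rng.uniform(2.3, 8.0)))
        if sampled["underdose"] == "severe":
            ratios.append(float(rng.uniform(0.15, 0.45)))
        elif sampled["underdose"] == "mild":
            ratios.append(float(rng.uniform(0.56, 0.75)))
        if not ratios:
            ratios.append(float(rng.uniform(0.9, 1.1)))

        shift: Optional[str] = None
        if (sampled["overdose"] == "none" and sampled["underdose"] == "none"
                and rng.random() < noise.decimal_shift_rate):
            shift = "up" if rng.random() < 0.5 else "down"
            doses = [inject_decimal_shift(round(rec, 4), shift)]
        else:
            doses = []
            for r in ratios:
                d = r * rec
                if noise.rounding_jitter:
                    d *= 1.0 + float(rng.uniform(-noise.rounding_jitter, noise.rounding_jitter))
                doses.append(max(round(d, 4), 0.0001))

        times = [first_time]
        for _ in doses[1:]:
            times.append(times[-1] + timedelta(seconds=int(rng.integers(120, 300))))

        over, under = _gold_dosing(doses, weight)
        labels = {"overdose": over, "underdose": under,
                  "delay": _gold_delay(times[0], arrival, arrest)}

        # --- realize the chart document ----------------------------------
        narrative_parts: list[str] = [_pick(rng, _FLAVOR_POOL)]
        structured: dict[str, Any] = {}
        meds: list[dict[str, Any]] = []

        def narrative_only() -> bool:
            return bool(rng.random() < noise.narrative_rate)

        if narrative_only():
            narrative_parts.append(_pick(rng, _AGE_POOL).format(a=age))
        else:
            structured["age_years"] = age
        if narrative_only():
            narrative_parts.append(_pick(rng, _WEIGHT_POOL).format(w=f"{weight:g}"))
        else:
            structured["weight_kg"] = weight
        times_section: dict[str, str] = {}
        if narrative_only():
            narrative_parts.append(_pick(rng, _ARRIVAL_POOL).format(t=arrival.isoformat()))
        else:
            times_section["unit_arrival"] = arrival.isoformat()
        if narrative_only():
            narrative_parts.append(_pick(rng, _ARREST_POOL).format(t=arrest.isoformat()))
        else:
            times_section["arrest_onset"] = arrest.isoformat()
        for dose, t in zip(doses, times):
            if narrative_only():
                narrative_parts.append(
                    _pick(rng, _ADMIN_POOL).format(d=f"{dose:g}", t=t.isoformat()))
            else:
                meds.append({"name": "epinephrine", "dose": dose, "unit": "mg",
                             "route": "IV", "time": t.isoformat()})

        conflicts: list[str] = []
        if rng.random() < noise.conflict_rate:
            if noise.conflict_field == "patient_weight":
                w2 = round(weight + 4.7, 1)
                narrative_parts.append(f"Weight documented elsewhere as {w2:g} kg.")
                conflicts.append("patient_weight")
            else:
                d2 = round(doses[0] * 2 + 0.01, 4)
                narrative_parts.append(
                    f"Epinephrine {d2:g} mg given at {times[0].isoformat()}.")
                conflicts.append("administered_dose")

        record = {
            "chart_id": chart_id,
            "patient": structured,
            "times": times_section,
            "medications": meds,
            "narrative": " ".join(narrative_parts),
        }
        charts.append(read_chart(record))
        gold.append(GoldRecord(
            chart_id=chart_id, labels=labels, age_years=age, weight_kg=weight,
            unit_arrival=arrival, arrest_onset=arrest,
            administrations=list(zip(doses, times)),
            conflict_fields=conflicts, decimal_shift=shift,
        ))
    return charts, gold


def write_cohort(
    charts: list[ClinicalChart],
    gold: list[GoldRecord],
    outdir: str | Path,
    *,
    config: Optional[CohortConfig] = None,
) -> None:
    """Write charts (one JSON per chart), gold labels (CSV), field truth
    (JSON), and a run manifest recording the generating config."""
    out = Path(outdir)
    (out / "charts").mkdir(parents=True, exist_ok=True)
    for chart in charts:
        doc = {
            "chart_id": chart.chart_id,
            "patient": {k: v for k, v in
                        (("age_years", chart.age_years), ("weight_kg", chart.weight_kg))
                        if v is not None},
            "times": {k: v.isoformat() for k, v in
                      (("unit_arrival", chart.unit_arrival_time),
                       ("arrest_onset", chart.arrest_onset_time)) if v is not None},
            "medications": [
                {"name": a.drug_name, "dose": a.dose_value, "unit": a.dose_unit,
                 "route": a.route, "time": a.time.isoformat() if a.time else None}
                for a in chart.administrations
            ],
            "narrative": chart.narrative,
        }
        (out / "charts" / f"{chart.chart_id}.json").write_text(json.dumps(doc, indent=1))
    pd.DataFrame(
        [{"chart_id": g.chart_id, **g.labels} for g in gold]
    ).to_csv(out / "gold.csv", index=False)
    (out / "truth.json").write_text(json.dumps(
        {g.chart_id: g.truth_fields() for g in gold}, indent=1))
    if config is not None:
        (out / "manifest.json").write_text(json.dumps(
            {"generator": "emsafe.simulate", "config": config.model_dump()}, indent=1))
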