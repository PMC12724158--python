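# emsafe

Ontology-driven, explainable detection of **epinephrine adverse safety
events** (ASEs) — overdose, underdose, and delayed administration — in EMS
patient-care charts for pediatric out-of-hospital cardiac arrest.

## Who this is for

Patient-safety and quality-improvement teams reviewing prehospital charts.
Manual chart review by clinicians is the gold standard for ASE detection but
is slow and samples only a fraction of charts; purely pattern-based models
are unreliable precisely on the rare, high-stakes events that matter.
`emsafe` takes a third path: a language model is used **only** to extract
facts from the chart text, and the clinical decision is made by executing a
verified computational graph of guideline rules, so every determination is
deterministic and traceable node by node.

## The model

The clinical knowledge is an *ontology*: a typed directed acyclic graph
whose input nodes are chart facts (weight `w` in kg, administered dose `d`
in mg, event times), whose derived nodes are guideline quantities, and whose
output nodes are the determinations. For pediatric pulseless arrest, PALS
recommends epinephrine at 0.01 mg/kg, so with dose ratio
`r = d / (0.01 · w)` and elapsed times `t_arrival`, `t_arrest` (minutes from
EMS arrival and from arrest onset to the first dose):

| category  | mild                        | severe                      |
|-----------|-----------------------------|-----------------------------|
| overdose  | `r ≥ 2`                     | `r ≥ 10`                    |
| underdose | `r ≤ 0.8`                   | `r ≤ 0.5`                   |
| delay     | `min(t_arrival, t_arrest) ≥ 5 min` | `min(·,·) ≥ 10 min`  |

Boundaries are inclusive and evaluated with a 1e-9 relative tolerance so a
one-decimal-place transcription error (exactly 10× the correct dose, a
common real-world failure) always classifies as severe.

The pipeline per chart: (1) structured fields are verbalized through
templates ("the patient weighs 12 kg") and the narrative is sentence-
tokenized into one document; (2) a schema-constrained zero-shot extractor
fills one slot per input node, **abstaining** (`not_found` /
`conflicting_values`) rather than guessing — a deterministic offline mock
backend is bundled, and any external LLM can be plugged in behind the same
stateless contract; (3) the rule engine backward-chains from the requested
determination, coerces values to each node's declared type and unit, and
executes only verified rules, recording a full per-node trace; missing or
abstained inputs propagate as errors with the origin node attached, never as
fabricated values.

Rules live as plain Python source files with a sha256 manifest and a gated
lifecycle (`generated → sandbox_checked → verified`); the sandbox is a
static denylist plus compile check plus a time-limited probe in a
subprocess.

Because no chart dataset ships with the package, `emsafe.simulate` generates
NEMSIS-dialect cohorts with known gold labels and configurable documentation
noise (conflicting duplicate values, decimal-shift dose errors,
narrative-only facts), and `emsafe.evaluation` provides the scoring surface:
per-category confusion matrices, NA-aware accuracy/precision/recall/F, and
the agreement coefficients used for gold standards built by dual review —
Gwet's AC1 (robust at low prevalence) alongside Cohen's kappa.

## Worked example

```python
from emsafe import read_chart, review_chart

chart = read_chart({
    "chart_id": "EX-001",
    "patient": {"age_years": 4, "weight_kg": 16.0},
    "times": {"unit_arrival": "2026-03-15T10:00:00+00:00",
              "arrest_onset": "2026-03-15T09:57:00+00:00"},
    "medications": [{"name": "epinephrine", "dose": 1.6, "unit": "mg",
                     "route": "IV", "time": "2026-03-15T10:04:00+00:00"}],
    "narrative": "Pt found pulseless. Bystander CPR in progress on arrival.",
})
det = review_chart(chart)
```

printing the determination (`examples/01_review_single_chart.py`):

```
overdose  -> severe
            administered_dose_mg = 1.6
            recommended_dose_mg = 0.16
            dose_ratio = 10.0
underdose -> none
            ...
delay     -> none
            delay_from_arrival_min = 4.0
            delay_from_arrest_min = 7.0
            effective_delay_min = 4.0
```

The 16 kg patient's recommended dose is 0.16 mg; the recorded 1.6 mg is a
dose ratio of exactly 10.0, the inclusive severe-overdose boundary — the
decimal-error signature. The first dose came 4 minutes after arrival, below
the 5-minute mild-delay threshold, so delay is `none`. Every number above is
read off the execution trace, which also records error origins when inputs
are missing (see `examples/04_execution_traces.py`).

More examples: `examples/02_cohort_evaluation.py` (synthetic cohort →
review → scored report) and `examples/03_agreement_statistics.py` (AC1 vs
kappa as prevalence shrinks).

There is also a thin CLI: `emsafe simulate`, `emsafe review`,
`emsafe evaluate`, `emsafe validate-ontology`.

## Layout

```
src/emsafe/        ontology, ingest, extraction, engine, epi, pipeline,
                   evaluation, simulate, cli  (+ data/: bundled ontology
                   YAML and verified rule sources with manifest)
tests/             unit, property, and acceptance suites
examples/          one narrative script per capability
docs/methods.md    modeling assumptions, parameters, limitations
```
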