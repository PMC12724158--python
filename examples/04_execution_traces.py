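"""Traceable error propagation when a required input is missing.

A chart without a documented weight cannot support a dosing determination.
Instead of guessing, the engine records a missing input at the weight node
and propagates the error to every descendant, so the final determination
carries the exact origin of the failure.
"""
import json

from emsafe import bundled_ontology, bundled_registry, execute

onto = bundled_ontology()
registry = bundled_registry()

trace = execute(
    onto,
    {"administered_dose": (0.5, "mg")},  # weight withheld
    "overdose_ase",
    registry,
)

print(json.dumps(trace.to_dict(), indent=2))
# Every node from recommended_dose onward reports the same origin
# (patient_weight), the explainability surface a reviewing clinician sees.
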