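"""Review one EMS chart for epinephrine adverse safety events.

Builds a small pediatric cardiac-arrest chart (structured fields plus a
narrative), runs the full pipeline — sentence assembly, mock zero-shot
extraction, rule-graph execution — and prints the per-category
determination with its supporting quantities.
"""
from emsafe import read_chart, review_chart

chart = read_chart({
    "chart_id": "EX-001",
    "patient": {"age_years": 4, "weight_kg": 16.0},
    "times": {
        "unit_arrival": "2026-03-15T10:00:00+00:00",
        "arrest_onset": "2026-03-15T09:57:00+00:00",
    },
    "medications": [
        # recommended dose at 16 kg is 0.16 mg; 1.6 mg is a 10x decimal error
        {"name": "epinephrine", "dose": 1.6, "unit": "mg", "route": "IV",
         "time": "2026-03-15T10:04:00+00:00"},
    ],
    "narrative": "Pt found pulseless. Bystander CPR in progress on arrival.",
})

det = review_chart(chart)
for category in ("overdose", "underdose", "delay"):
    res = det.categories[category]
    print(f"{category:9s} -> {res.severity}")
    for key, value in res.evidence.items():
        print(f"            {key} = {value}")

# The dose ratio of 10.0 sits exactly at the severe-overdose threshold:
# boundaries are inclusive, so a one-decimal-place transcription error on a
# correct dose is always flagged severe. Delay is 4 minutes from arrival
# (and 7 from arrest onset), below the 5-minute mild threshold.
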