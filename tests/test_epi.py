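"""Epinephrine dosing/delay classification and chart-level determination."""
from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings, strategies as st

from emsafe.epi import (
    ASEDetermination,
    classify_delay,
    classify_overdose,
    classify_underdose,
    delay_minutes,
    determine_chart,
    dose_ratio,
    recommended_dose,
)
from emsafe.extraction import (
    Abstention,
    AdministrationFact,
    ExtractedValue,
    ExtractionResult,
)

T0 = datetime(2026, 3, 15, 10, 0, 0, tzinfo=timezone.utc)


class TestDoseArithmetic:
    @pytest.mark.parametrize("weight, expected", [(10.0, 0.1), (1.0, 0.01), (22.5, 0.225)])
    def test_recommended_dose_is_hundredth_of_weight(self, weight, expected):
        assert recommended_dose(weight) == pytest.approx(expected)

    @pytest.mark.parametrize("weight", [0.0, -5.0])
    def test_nonpositive_weight_rejected(self, weight):
        with pytest.raises(ValueError):
            recommended_dose(weight)

    @pytest.mark.parametrize("adm, rec, expected", [
        (1.0, 0.1, 10.0), (0.1, 0.1, 1.0), (0.0, 0.1, 0.0),
    ])
    def test_dose_ratio(self, adm, rec, expected):
        assert dose_ratio(adm, rec) == pytest.approx(expected)

    def test_nonpositive_recommended_rejected(self):
        with pytest.raises(ValueError):
            dose_ratio(1.0, 0.0)


class TestClassifiers:
    @pytest.mark.parametrize("ratio, severity", [
        (10.0, "severe"), (11.0, "severe"),
        (2.0, "mild"), (9.99, "mild"),
        (1.99, "none"), (1.0, "none"), (0.0, "none"),
    ])
    def test_overdose_boundaries_inclusive(self, ratio, severity):
        assert classify_overdose(ratio) == severity

    @pytest.mark.parametrize("ratio, severity", [
        (0.5, "severe"), (0.1, "severe"),
        (0.8, "mild"), (0.51, "mild"),
        (0.81, "none"), (1.0, "none"),
    ])
    def test_underdose_boundaries_inclusive(self, ratio, severity):
        assert classify_underdose(ratio) == severity

    def test_zero_ratio_is_not_an_underdose(self):
        with pytest.raises(ValueError, match="non-administration"):
            classify_underdose(0.0)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_overdose(-0.1)

    def test_near_threshold_float_ratio_still_severe(self):
        # a 10x decimal-shift error computed through floating point
        ratio = (10 * 0.225) / 0.225
        assert classify_overdose(ratio) == "severe"

    def test_overdose_boundary_sweep_changes_exactly_at_2_and_10(self):
        changes = []
        prev = classify_overdose(0.0)
        for i in range(1, 1201):
            cur = classify_overdose(i / 100)
            if cur != prev:
                changes.append(i / 100)
                prev = cur
        assert changes == [2.0, 10.0]

    def test_underdose_boundary_sweep_changes_exactly_at_half_and_08(self):
        changes = []
        prev = classify_underdose(0.01)
        for i in range(2, 121):
            cur = classify_underdose(i / 100)
            if cur != prev:
                changes.append(i / 100)
                prev = cur
        assert changes == [0.51, 0.81]

    @given(st.floats(min_value=0, max_value=20, allow_nan=False))
    @settings(max_examples=80, derandomize=True)
    def test_severe_overdose_implies_mild_criterion(self, ratio):
        # nesting: severe threshold (10) lies inside the mild one (2)
        if classify_overdose(ratio) == "severe":
            assert ratio >= 2.0 * (1 - 1e-9)

    @given(st.floats(min_value=0.001, max_value=20, allow_nan=False),
           st.floats(min_value=0, max_value=5, allow_nan=False))
    @settings(max_examples=80, derandomize=True)
    def test_monotonic_in_ratio_and_exclusive(self, ratio, bump):
        rank = {"none": 0, "mild": 1, "severe": 2}
        assert rank[classify_overdose(ratio + bump)] >= rank[classify_overdose(ratio)]
        assert rank[classify_underdose(ratio + bump)] <= rank[classify_underdose(ratio)]
        # one administration cannot be both an overdose and an underdose
        assert not (rank[classify_overdose(ratio)] > 0 and rank[classify_underdose(ratio)] > 0)


class TestDelay:
    def test_elapsed_minutes(self):
        fa, fr = delay_minutes(T0 + timedelta(minutes=10), T0, T0 - timedelta(minutes=5))
        assert (fa, fr) == (10.0, 15.0)

    def test_dose_at_arrival_is_zero_minutes(self):
        fa, _ = delay_minutes(T0, T0)
        assert fa == 0.0

    def test_dose_before_arrival_is_an_error(self):
        with pytest.raises(ValueError):
            delay_minutes(T0 - timedelta(minutes=1), T0)

    @pytest.mark.parametrize("fa, fr, severity", [
        (12.0, 15.0, "severe"),
        (12.0, 4.0, "none"),   # AND-semantics: the arrest clock fails the threshold
        (5.0, 5.0, "mild"),
        (9.9, 60.0, "mild"),
        (4.9, 4.9, "none"),
    ])
    def test_both_clocks_must_exceed_threshold(self, fa, fr, severity):
        assert classify_delay(fa, fr) == severity

    def test_strict_policy_refuses_without_arrest_clock(self):
        with pytest.raises(ValueError, match="strict"):
            classify_delay(12.0, None)

    def test_arrival_only_policy_classifies_on_one_clock(self):
        assert classify_delay(12.0, None, policy="arrival_only") == "severe"

    @given(st.floats(min_value=0, max_value=30, allow_nan=False),
           st.floats(min_value=0, max_value=30, allow_nan=False))
    @settings(max_examples=80, derandomize=True)
    def test_classification_depends_on_minimum_clock(self, fa, fr):
        assert classify_delay(fa, fr) == classify_delay(min(fa, fr), min(fa, fr))


def result_for(weight=10.0, doses=(1.0,), epi_minutes=(3.0,), arrival=T0, arrest_gap=2.0):
    admins = tuple(
        AdministrationFact("epinephrine", arrival + timedelta(minutes=m), d, None, (i,))
        for i, (d, m) in enumerate(zip(doses, epi_minutes))
    )
    first = min((a.time for a in admins), default=None)
    values = {
        "patient_weight": ExtractedValue(weight, "kg", (0,)),
        "ems_arrival_time": ExtractedValue(arrival, None, (1,)),
        "arrest_onset_time": ExtractedValue(arrival - timedelta(minutes=arrest_gap), None, (2,)),
        "first_epi_time": (ExtractedValue(first, None, (3,)) if first
                           else Abstention("not_found")),
        "administered_dose": ExtractedValue(list(doses), "mg", (3,)),
    }
    return ExtractionResult(values, admins)


class TestDetermineChart:
    def test_worst_severity_rolls_up_across_administrations(self, onto, registry):
        det = determine_chart("X", result_for(weight=10.0, doses=(1.0, 0.1),
                                              epi_minutes=(3.0, 6.0)),
                              ontology=onto, registry=registry)
        assert det.severity("overdose") == "severe"
        assert det.categories["overdose"].administration_index == 0
        assert det.severity("underdose") == "none"
        assert det.severity("delay") == "none"
        cats = [d.category for d in det.per_administration]
        assert cats.count("overdose") == 2 and cats.count("underdose") == 2

    def test_single_correct_prompt_dose_is_all_none(self, onto, registry):
        det = determine_chart("X", result_for(doses=(0.1,), epi_minutes=(3.0,)),
                              ontology=onto, registry=registry)
        assert [det.severity(c) for c in ("overdose", "underdose", "delay")] == ["none"] * 3

    def test_no_epinephrine_is_not_evaluated(self, onto, registry):
        res = ExtractionResult({"patient_weight": ExtractedValue(10.0, "kg", (0,))}, ())
        det = determine_chart("X", res, ontology=onto, registry=registry)
        for cat in ("overdose", "underdose", "delay"):
            assert det.severity(cat) is None
            assert det.categories[cat].skipped is not None

    def test_zero_dose_skips_underdose_but_not_overdose(self, onto, registry):
        det = determine_chart("X", result_for(doses=(0.0,)), ontology=onto, registry=registry)
        assert det.severity("overdose") == "none"
        assert det.severity("underdose") is None
        assert det.categories["underdose"].skipped is not None

    def test_abstained_weight_yields_traceable_error_not_a_value(self, onto, registry):
        res = result_for(doses=(1.0,))
        res.values["patient_weight"] = Abstention("conflicting_values")
        det = determine_chart("X", res, ontology=onto, registry=registry)
        for cat in ("overdose", "underdose"):
            assert det.severity(cat) is None
            assert det.categories[cat].error.origin == "patient_weight"
            assert det.categories[cat].error.kind == "missing_input"
        assert det.severity("delay") == "none"  # delay does not need weight

    def test_delay_evidence_reports_both_clocks(self, onto, registry):
        det = determine_chart("X", result_for(epi_minutes=(12.0,), arrest_gap=3.0),
                              ontology=onto, registry=registry)
        ev = det.categories["delay"].evidence
        assert ev["delay_from_arrival_min"] == pytest.approx(12.0)
        assert ev["delay_from_arrest_min"] == pytest.approx(15.0)
        assert ev["effective_delay_min"] == pytest.approx(12.0)
        assert det.severity("delay") == "severe"

    def test_arrival_only_policy_when_arrest_unknown(self, onto, registry):
        res = result_for(epi_minutes=(12.0,))
        res.values["arrest_onset_time"] = Abstention("not_found")
        strict = determine_chart("X", res, ontology=onto, registry=registry)
        assert strict.severity("delay") is None
        assert strict.categories["delay"].error.origin == "arrest_onset_time"
        loose = determine_chart("X", res, ontology=onto, registry=registry,
                                delay_policy="arrival_only")
        assert loose.severity("delay") == "severe"
        assert "arrival_only" in loose.categories["delay"].evidence["delay_policy"]

    def test_to_dict_serializes_evidence_and_errors(self, onto, registry):
        res = result_for(doses=(1.0,))
        res.values["patient_weight"] = Abstention("not_found")
        doc = determine_chart("X", res, ontology=onto, registry=registry).to_dict(
            include_traces=True)
        assert doc["categories"]["overdose"]["error"]["origin"] == "patient_weight"
        assert doc["categories"]["delay"]["severity"] == "none"
        assert doc["traces"]
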