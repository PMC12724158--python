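"""Rule lifecycle, sandbox checks, coercion, and trace execution."""
from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from emsafe.engine import (
    CoercionError,
    RuleDefinition,
    RuleRegistry,
    SandboxFailure,
    coerce,
    execute,
    generate_rule,
    promote_to_verified,
    sandbox_check,
)
from emsafe.epi import (
    classify_delay,
    classify_overdose,
    classify_underdose,
    delay_minutes,
    dose_ratio,
    recommended_dose,
)
from emsafe.ontology import ValueSpec, required_inputs

T0 = datetime(2026, 3, 15, 10, 0, 0, tzinfo=timezone.utc)


def make_rule(body, signature=(("x", "number"),), status="generated", rule_id="t"):
    return RuleDefinition(rule_id=rule_id, node_id="n", guideline_text="g",
                         body=body, signature=list(signature), status=status)


class TestCoerce:
    @pytest.mark.parametrize("raw, spec, expected", [
        ("0.1", ValueSpec(type="number"), 0.1),
        (3, ValueSpec(type="number"), 3.0),
        ((100, "mcg"), ValueSpec(type="quantity", unit="mg"), 0.1),
        ("100 mcg", ValueSpec(type="quantity", unit="mg"), 0.1),
        ({"value": 2, "unit": "h"}, ValueSpec(type="quantity", unit="min"), 120.0),
        (0.5, ValueSpec(type="quantity", unit="mg"), 0.5),  # bare number: declared unit
        ("true", ValueSpec(type="boolean"), True),
        ("mild", ValueSpec(type="categorical", levels=["none", "mild", "severe"]), "mild"),
    ])
    def test_coercions(self, raw, spec, expected):
        got = coerce(raw, spec)
        if isinstance(expected, float):
            assert got == pytest.approx(expected)
        else:
            assert got == expected

    def test_timestamp_parsing(self):
        got = coerce("2026-03-15T10:00:00Z", ValueSpec(type="timestamp"))
        assert got == T0

    @pytest.mark.parametrize("raw, spec", [
        ("twelve", ValueSpec(type="number")),
        ((1, "kg"), ValueSpec(type="quantity", unit="mg")),  # cross-dimension
        ("sorta", ValueSpec(type="boolean")),
        ("huge", ValueSpec(type="categorical", levels=["none", "mild", "severe"])),
    ])
    def test_failures_raise_coercion_error(self, raw, spec):
        with pytest.raises(CoercionError):
            coerce(raw, spec)


class TestSandbox:
    def test_pure_arithmetic_passes(self):
        checked = sandbox_check(make_rule("def rule(x):\n    return x * 2\n"))
        assert isinstance(checked, RuleDefinition)
        assert checked.status == "sandbox_checked"

    def test_file_access_fails_static_check(self):
        out = sandbox_check(make_rule("def rule(x):\n    return open('/etc/passwd')\n"))
        assert isinstance(out, SandboxFailure) and out.check == "static"

    def test_import_fails_static_check(self):
        out = sandbox_check(make_rule("import os\ndef rule(x):\n    return 1\n"))
        assert isinstance(out, SandboxFailure) and out.check == "static"

    def test_dunder_access_fails_static_check(self):
        out = sandbox_check(make_rule("def rule(x):\n    return x.__class__\n"))
        assert isinstance(out, SandboxFailure) and out.check == "static"

    def test_infinite_loop_fails_timeout(self):
        out = sandbox_check(make_rule("def rule(x):\n    while True:\n        pass\n"),
                            probe_timeout=0.5)
        assert isinstance(out, SandboxFailure) and out.check == "timeout"

    def test_syntax_error_fails_compile(self):
        out = sandbox_check(make_rule("def rule(x:\n"))
        assert isinstance(out, SandboxFailure) and out.check == "compile"

    def test_undeclared_parameter_fails_signature(self):
        out = sandbox_check(make_rule("def rule(x, y):\n    return x\n"))
        assert isinstance(out, SandboxFailure) and out.check == "signature"


class TestRuleLifecycle:
    def test_generated_rule_is_never_auto_promoted(self):
        rule = generate_rule("double it", "n", [("x", "number")],
                             backend=lambda text, sig: "def rule(x):\n    return 2*x\n")
        assert rule.status == "generated"
        reg = RuleRegistry()
        with pytest.raises(ValueError, match="unverified"):
            reg.register(rule)

    def test_empty_guideline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_rule("  ", "n", [("x", "number")], backend=lambda t, s: "x")

    def test_syntax_diagnostics_attached(self):
        rule = generate_rule("bad", "n", [("x", "number")],
                             backend=lambda t, s: "def rule(x:\n")
        assert rule.diagnostics and "syntax" in rule.diagnostics[0]

    def test_full_promotion_path_then_registration(self):
        rule = generate_rule("double it", "n", [("x", "number")],
                             backend=lambda t, s: "def rule(x):\n    return 2*x\n")
        checked = sandbox_check(rule)
        verified = promote_to_verified(checked)
        reg = RuleRegistry().register(verified)
        assert reg.callable_for(verified.rule_id)(21) == 42

    def test_duplicate_rule_id_different_body_rejected(self):
        a = make_rule("def rule(x):\n    return x\n", status="verified", rule_id="dup")
        b = make_rule("def rule(x):\n    return x + 1\n", status="verified", rule_id="dup")
        reg = RuleRegistry().register(a)
        with pytest.raises(ValueError, match="different body"):
            reg.register(b)

    def test_same_body_reregistration_is_idempotent(self):
        a = make_rule("def rule(x):\n    return x\n", status="verified", rule_id="dup")
        reg = RuleRegistry().register(a)
        reg.register(a.model_copy())
        assert reg.rule_ids() == ["dup"]

    def test_promotion_requires_sandbox_check(self):
        with pytest.raises(ValueError, match="sandbox_checked"):
            promote_to_verified(make_rule("def rule(x):\n    return x\n"))


def full_inputs(weight=10.0, dose=1.0, epi_min=3.0, arrival=T0, arrest_gap_min=2.0):
    return {
        "patient_weight": weight,
        "administered_dose": (dose, "mg"),
        "first_epi_time": arrival + timedelta(minutes=epi_min),
        "ems_arrival_time": arrival,
        "arrest_onset_time": arrival - timedelta(minutes=arrest_gap_min),
    }


class TestExecute:
    def test_overdose_trace_ends_in_severity(self, onto, registry):
        trace = execute(onto, full_inputs(weight=10.0, dose=1.0), "overdose_ase", registry)
        assert trace.outcome.ok and trace.outcome.value == "severe"
        assert trace.value_of("recommended_dose") == pytest.approx(0.1)
        assert trace.value_of("dose_ratio") == pytest.approx(10.0)

    def test_missing_weight_propagates_with_origin(self, onto, registry):
        inputs = full_inputs()
        del inputs["patient_weight"]
        trace = execute(onto, inputs, "overdose_ase", registry)
        assert trace.entry("patient_weight").error.kind == "missing_input"
        out = trace.outcome
        assert not out.ok and out.error.origin == "patient_weight"
        assert out.error.kind == "missing_input"

    def test_lazy_subgraph_excludes_other_category_nodes(self, onto, registry):
        trace = execute(onto, full_inputs(), "delay_ase", registry)
        nodes = {e.node_id for e in trace.entries}
        assert "administered_dose" not in nodes and "dose_ratio" not in nodes

    def test_trace_complete_and_in_chain_order(self, onto, registry):
        from emsafe.ontology import backward_chain
        trace = execute(onto, full_inputs(), "delay_ase", registry)
        assert [e.node_id for e in trace.entries] == backward_chain(onto, "delay_ase")

    def test_referential_transparency(self, onto, registry):
        a = execute(onto, full_inputs(), "underdose_ase", registry)
        b = execute(onto, full_inputs(), "underdose_ase", registry)
        assert a == b

    def test_unknown_rule_ref_is_rule_error_entry(self, onto):
        trace = execute(onto, full_inputs(), "overdose_ase", RuleRegistry())
        assert trace.outcome.error.kind == "rule_error"

    def test_coercion_failure_recorded_at_input(self, onto, registry):
        inputs = full_inputs()
        inputs["patient_weight"] = "twelve"
        trace = execute(onto, inputs, "overdose_ase", registry)
        assert trace.entry("patient_weight").error.kind == "coercion_failure"
        assert trace.outcome.error.origin == "patient_weight"

    def test_error_origin_soundness_for_every_withheld_input(self, onto, registry):
        for target in ("overdose_ase", "underdose_ase", "delay_ase"):
            for missing in sorted(required_inputs(onto, target)):
                inputs = full_inputs()
                del inputs[missing]
                trace = execute(onto, inputs, target, registry)
                assert not trace.outcome.ok
                assert trace.outcome.error.origin == missing

    def test_trace_json_export_round_trips_outcome(self, onto, registry):
        doc = execute(onto, full_inputs(), "overdose_ase", registry).to_dict()
        assert doc["target"] == "overdose_ase"
        assert doc["outcome"] == "severe"
        assert doc["entries"][-1]["node"] == "overdose_ase"


class TestEngineAgainstReference:
    """The graph execution must equal a straight-line hand computation."""

    def test_random_valid_vectors_agree(self, onto, registry):
        rng = np.random.default_rng(2026)
        for _ in range(200):
            w = float(rng.uniform(3, 60))
            ratio = float(rng.uniform(0.01, 12.0))
            rec = recommended_dose(w)
            dose = ratio * rec
            epi_min = float(rng.uniform(0, 15))
            gap = float(rng.uniform(0, 10))
            inputs = full_inputs(weight=w, dose=dose, epi_min=epi_min, arrest_gap_min=gap)

            assert execute(onto, inputs, "overdose_ase", registry).outcome.value == \
                classify_overdose(dose_ratio(dose, rec))
            assert execute(onto, inputs, "underdose_ase", registry).outcome.value == \
                classify_underdose(dose_ratio(dose, rec))
            fa, fr = delay_minutes(inputs["first_epi_time"], inputs["ems_arrival_time"],
                                   inputs["arrest_onset_time"])
            assert execute(onto, inputs, "delay_ase", registry).outcome.value == \
                classify_delay(fa, fr)
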