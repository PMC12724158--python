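"""Verified executable rules and deterministic graph execution.

A rule is a small piece of Python source defining ``rule(<params>)`` whose
parameters are the target node's dependencies, in order.  Rules move through
a gated lifecycle — ``generated`` (possibly by a code-writing backend) →
``sandbox_checked`` (compiles, passes a static denylist, survives a
time-limited probe run) → ``verified`` (explicitly promoted, normally after
human review).  Only verified rules execute; the bundled epinephrine rules
ship pre-verified as source files with a sha256 manifest.

The sandbox is a desk-scale boundary, not OS-level isolation: it denies
imports, I/O, process, and reflection primitives statically, executes with a
stripped builtins table, and probes the rule in a forked subprocess under a
timeout.  Treat it as protection against accidents and obviously hostile
generated code, not a jail for a determined adversary.

Execution walks the backward-chained subgraph in deterministic topological
order.  Extracted values are coerced to each node's declared type and unit
first; a missing or abstained input, a coercion failure, or a raising rule
becomes an error *entry* in the trace — never an exception — and every
descendant carries a propagated error referencing the original failing node,
so a clinician can trace any determination back to its origin.
"""
from __future__ import annotations

import ast
import builtins
import hashlib
import inspect
import json
import multiprocessing
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, Field

from .extraction import Abstention, ExtractedValue, ExtractionResult
from .ingest import parse_timestamp
from .ontology import Ontology, ValueSpec, backward_chain
from .units import UnitError, convert

__all__ = [
    "RuleDefinition",
    "RuleRegistry",
    "SandboxFailure",
    "CoercionError",
    "TraceError",
    "TraceEntry",
    "ExecutionTrace",
    "generate_rule",
    "sandbox_check",
    "promote_to_verified",
    "coerce",
    "execute",
    "bundled_registry",
]


class RuleDefinition(BaseModel):
    rule_id: str
    node_id: str
    guideline_text: str
    body: str
    signature: list[tuple[str, str]]  # (parameter name, value kind)
    status: str = "generated"         # generated | sandbox_checked | verified
    diagnostics: list[str] = Field(default_factory=list)

    @property
    def body_sha256(self) -> str:
        return hashlib.sha256(self.body.encode()).hexdigest()


@dataclass(frozen=True)
class SandboxFailure:
    check: str    # "compile" | "static" | "probe" | "timeout" | "signature"
    detail: str


# ---------------------------------------------------------------------------
# Sandbox
# ---------------------------------------------------------------------------

_DENIED_NAMES = {
    "open", "exec", "eval", "compile", "__import__", "input", "breakpoint",
    "globals", "locals", "vars", "getattr", "setattr", "delattr", "dir",
    "memoryview", "exit", "quit", "help", "type", "super", "object",
    "os", "sys", "subprocess", "socket", "shutil", "pathlib", "importlib",
    "ctypes", "signal", "threading", "multiprocessing",
}

_SAFE_BUILTINS = {
    name: getattr(builtins, name)
    for name in (
        "abs", "min", "max", "round", "sum", "len", "sorted", "range",
        "float", "int", "str", "bool", "list", "dict", "tuple", "set",
        "enumerate", "zip", "isinstance", "ValueError", "TypeError",
        "ZeroDivisionError", "ArithmeticError", "Exception", "True", "False",
        "None",
        )
    if hasattr(builtins, name)
}


def _static_scan(tree: ast.AST) -> Optional[str]:
    """Return a violation description, or None if the body passes."""
    for node in ast.walk(tree):
        if isinstance(node, (ast.Import, ast.ImportFrom)):
            return "import statements are denied"
        if isinstance(node, (ast.Global, ast.Nonlocal)):
            return "global/nonlocal are denied"
        if isinstance(node, ast.Name) and node.id in _DENIED_NAMES:
            return f"use of denied name {node.id!r}"
        if isinstance(node, ast.Name) and node.id.startswith("__"):
            return f"dunder name {node.id!r} is denied"
        if isinstance(node, ast.Attribute) and node.attr.startswith("__"):
            return f"dunder attribute {node.attr!r} is denied"
    return None


def _compile_rule(rule: RuleDefinition) -> Any:
    """Compile a rule body in a restricted namespace and return ``rule``."""
    code = compile(rule.body, f"<rule:{rule.rule_id}>", "exec")
    ns: dict[str, Any] = {"__builtins__": _SAFE_BUILTINS}
    exec(code, ns)
    fn = ns.get("rule")
    if not callable(fn):
        raise ValueError(f"rule {rule.rule_id!r} does not define a callable 'rule'")
    params = list(inspect.signature(fn).parameters)
    expected = [name for name, _ in rule.signature]
    if params != expected:
        raise ValueError(
            f"rule {rule.rule_id!r} parameters {params} do not match signature {expected}"
        )
    return fn


_PLACEHOLDERS = {
    "number": 1.0,
    "quantity": 1.0,
    "timestamp": datetime(2020, 1, 1, 12, 0, 0),
    "boolean": True,
    "categorical": "none",
}


def _probe_child(body: str, args: list[Any]) -> None:  # pragma: no cover - runs in fork
    ns: dict[str, Any] = {"__builtins__": _SAFE_BUILTINS}
    exec(compile(body, "<probe>", "exec"), ns)
    try:
        ns["rule"](*args)
    except Exception:
        pass  # a clean domain exception is an acceptable probe outcome


def sandbox_check(rule: RuleDefinition, *, probe_timeout: float = 1.0) -> Union[RuleDefinition, SandboxFailure]:
    """Check a generated rule: compile, static denylist, timed probe run.

    Returns a ``sandbox_checked`` copy on success, or a :class:`SandboxFailure`
    naming the violated check.  The probe executes the rule once on
    type-appropriate placeholder inputs in a forked subprocess; an infinite
    loop or hang fails with ``timeout``.
    """
    if rule.status != "generated":
        raise ValueError(f"sandbox_check expects a generated rule, got status {rule.status!r}")
    try:
        tree = ast.parse(rule.body)
    except SyntaxError as exc:
        return SandboxFailure("compile", str(exc))
    violation = _static_scan(tree)
    if violation:
        return SandboxFailure("static", violation)
    try:
        _compile_rule(rule)
    except ValueError as exc:
        return SandboxFailure("signature", str(exc))

    args = [_PLACEHOLDERS[kind] for _, kind in rule.signature]
    ctx = multiprocessing.get_context("fork")
    proc = ctx.Process(target=_probe_child, args=(rule.body, args))
    proc.start()
    proc.join(probe_timeout)
    if proc.is_alive():
        proc.terminate()
        proc.join()
        return SandboxFailure("timeout", f"probe exceeded {probe_timeout}s")
    if proc.exitcode != 0:
        return SandboxFailure("probe", f"probe exited with code {proc.exitcode}")
    return rule.model_copy(update={"status": "sandbox_checked"})


def promote_to_verified(rule: RuleDefinition) -> RuleDefinition:
    """Explicit promotion step (stands in for human review sign-off)."""
    if rule.status != "sandbox_checked":
        raise ValueError("only sandbox_checked rules can be promoted to verified")
    return rule.model_copy(update={"status": "verified"})


def generate_rule(
    guideline_text: str,
    node_id: str,
    signature: Sequence[tuple[str, str]],
    backend,
    *,
    rule_id: Optional[str] = None,
) -> RuleDefinition:
    """Ask a code-writing backend to translate guideline text into a rule body.

    The result always has status ``generated`` — it is never auto-promoted —
    and carries compile diagnostics when the body does not parse.
    ``backend`` is any callable ``(guideline_text, signature) -> source``.
    """
    if not guideline_text or not guideline_text.strip():
        raise ValueError("guideline text is empty")
    body = backend(guideline_text, list(signature))
    diagnostics: list[str] = []
    try:
        ast.parse(body)
    except SyntaxError as exc:
        diagnostics.append(f"syntax error: {exc}")
    return RuleDefinition(
        rule_id=rule_id or f"{node_id}_generated",
        node_id=node_id,
        guideline_text=guideline_text,
        body=body,
        signature=list(signature),
        status="generated",
        diagnostics=diagnostics,
    )


class RuleRegistry:
    """Immutable store of verified rules, keyed by rule id."""

    def __init__(self) -> None:
        self._rules: dict[str, RuleDefinition] = {}
        self._fns: dict[str, Any] = {}

    def register(self, rule: RuleDefinition) -> "RuleRegistry":
        if rule.status != "verified":
            raise ValueError(f"refusing to register unverified rule {rule.rule_id!r} "
                             f"(status {rule.status!r})")
        existing = self._rules.get(rule.rule_id)
        if existing is not None:
            if existing.body_sha256 != rule.body_sha256:
                raise ValueError(f"rule {rule.rule_id!r} already registered with a different body")
            return self  # idempotent re-registration
        self._fns[rule.rule_id] = _compile_rule(rule)
        self._rules[rule.rule_id] = rule
        return self

    def get(self, rule_ref: str) -> RuleDefinition:
        return self._rules[rule_ref]

    def callable_for(self, rule_ref: str):
        return self._fns[rule_ref]

    def __contains__(self, rule_ref: str) -> bool:
        return rule_ref in self._rules

    def rule_ids(self) -> list[str]:
        return sorted(self._rules)


def bundled_registry() -> RuleRegistry:
    """Registry of the packaged, pre-verified epinephrine rules.

    Each rule body is read from its source file and checked against the
    manifest's sha256 before registration, so silent tampering is detected.
    """
    base = resources.files("emsafe").joinpath("data/rules")
    manifest = json.loads(base.joinpath("manifest.json").read_text())
    reg = RuleRegistry()
    for entry in manifest["rules"]:
        body = base.joinpath(entry["file"]).read_text()
        digest = hashlib.sha256(body.encode()).hexdigest()
        if digest != entry["sha256"]:
            raise ValueError(f"rule file {entry['file']} does not match manifest sha256")
        reg.register(RuleDefinition(
            rule_id=entry["rule_id"],
            node_id=entry["node_id"],
            guideline_text=entry["guideline_text"],
            body=body,
            signature=[tuple(p) for p in entry["signature"]],
            status=entry["status"],
        ))
    return reg


# ---------------------------------------------------------------------------
# Coercion
# ---------------------------------------------------------------------------

class CoercionError(ValueError):
    pass


def coerce(raw: Any, spec: ValueSpec) -> Any:
    """Coerce a raw extracted value to a node's declared type.

    Numbers parse from numeric strings; quantities accept a bare number
    (taken in the declared unit), a ``(value, unit)`` pair, a
    ``{"value":..,"unit":..}`` mapping, or a ``"100 mcg"`` string, and are
    unit-converted to the declared unit; timestamps parse ISO-8601.
    Anything else raises :class:`CoercionError`.
    """
    try:
        if spec.type == "number":
            if isinstance(raw, bool) or isinstance(raw, (int, float)):
                return float(raw)
            return float(str(raw).strip())
        if spec.type == "quantity":
            value, unit = raw, spec.unit
            if isinstance(raw, (tuple, list)) and len(raw) == 2:
                value, unit = raw
            elif isinstance(raw, Mapping):
                value, unit = raw["value"], raw.get("unit", spec.unit)
            elif isinstance(raw, str):
                parts = raw.strip().split()
                if len(parts) == 2:
                    value, unit = parts
            return convert(float(value), str(unit), str(spec.unit))
        if spec.type == "timestamp":
            return parse_timestamp(raw)
        if spec.type == "boolean":
            if isinstance(raw, bool):
                return raw
            s = str(raw).strip().lower()
            if s in ("true", "yes", "1"):
                return True
            if s in ("false", "no", "0"):
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        if spec.type == "categorical":
            s = str(raw)
            if spec.levels and s not in spec.levels:
                raise ValueError(f"{s!r} is not among declared levels {spec.levels}")
            return s
    except (TypeError, ValueError, KeyError, UnitError) as exc:
        raise CoercionError(f"cannot coerce {raw!r} to {spec.type}"
                            + (f" [{spec.unit}]" if spec.unit else "") + f": {exc}") from exc
    raise CoercionError(f"unknown value type {spec.type!r}")


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceError:
    kind: str    # "missing_input" | "coercion_failure" | "rule_error"
    origin: str  # node id of the first failing ancestor
    detail: str = ""


@dataclass(frozen=True)
class TraceEntry:
    node_id: str
    value: Any = None
    error: Optional[TraceError] = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class ExecutionTrace:
    """Ordered record of every evaluated node — the explainability surface."""

    target: str
    entries: tuple[TraceEntry, ...]

    @property
    def outcome(self) -> TraceEntry:
        return self.entries[-1]

    def entry(self, node_id: str) -> TraceEntry:
        for e in self.entries:
            if e.node_id == node_id:
                return e
        raise KeyError(node_id)

    def value_of(self, node_id: str) -> Any:
        return self.entry(node_id).value

    def to_dict(self) -> dict[str, Any]:
        def render(v: Any) -> Any:
            return v.isoformat() if isinstance(v, datetime) else v

        entries = []
        for e in self.entries:
            item: dict[str, Any] = {"node": e.node_id}
            if e.ok:
                item["value"] = render(e.value)
            else:
                item["error"] = {"kind": e.error.kind, "origin": e.error.origin,
                                 "detail": e.error.detail}
            entries.append(item)
        return {"target": self.target, "entries": entries,
                "outcome": entries[-1].get("value"),
                "error": entries[-1].get("error")}


def _raw_input(inputs: Any, node_id: str) -> Any:
    if isinstance(inputs, ExtractionResult):
        v = inputs.values.get(node_id)
        if v is None or isinstance(v, Abstention):
            return v
        return (v.value, v.unit) if v.unit is not None else v.value
    return inputs.get(node_id)


def execute(
    onto: Ontology,
    inputs: Union[Mapping[str, Any], ExtractionResult],
    target: str,
    registry: RuleRegistry,
) -> ExecutionTrace:
    """Evaluate the backward-chained subgraph of ``target`` over ``inputs``.

    ``inputs`` maps input node ids to raw values (or is an
    :class:`ExtractionResult`, whose abstentions count as missing).  Returns
    a complete trace in deterministic topological order; all failures are
    encoded as trace entries with a propagated origin, never raised.
    """
    order = backward_chain(onto, target)
    entries: list[TraceEntry] = []
    by_id: dict[str, TraceEntry] = {}

    for nid in order:
        node = onto.nodes[nid]
        if node.kind == "input":
            raw = _raw_input(inputs, nid)
            if raw is None:
                entry = TraceEntry(nid, error=TraceError("missing_input", nid, "no value provided"))
            elif isinstance(raw, Abstention):
                entry = TraceEntry(nid, error=TraceError(
                    "missing_input", nid, f"extraction abstained: {raw.reason}"))
            else:
                try:
                    entry = TraceEntry(nid, value=coerce(raw, node.value_type))
                except CoercionError as exc:
                    entry = TraceEntry(nid, error=TraceError("coercion_failure", nid, str(exc)))
        else:
            failed = next((by_id[d] for d in order if d in node.depends_on
                           and not by_id[d].ok), None)
            if failed is not None:
                entry = TraceEntry(nid, error=TraceError(
                    failed.error.kind, failed.error.origin,
                    f"propagated from {failed.node_id}"))
            elif node.rule_ref not in registry:
                entry = TraceEntry(nid, error=TraceError(
                    "rule_error", nid, f"no verified rule registered for {node.rule_ref!r}"))
            else:
                fn = registry.callable_for(node.rule_ref)
                args = [by_id[d].value for d in node.depends_on]
                try:
                    result = fn(*args)
                    entry = TraceEntry(nid, value=coerce(result, node.value_type))
                except Exception as exc:
                    entry = TraceEntry(nid, error=TraceError("rule_error", nid, str(exc)))
        entries.append(entry)
        by_id[nid] = entry
    return ExecutionTrace(target, tuple(entries))
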