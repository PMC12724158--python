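"""Clinical concept ontologies as typed computational graphs.

An :class:`Ontology` is a directed acyclic graph of :class:`ConceptNode`
objects.  *Input* nodes are facts retrieved from a chart (patient weight,
administered doses, event times); *derived* nodes are intermediate
quantities computed by executable rules (recommended dose, dose ratio,
elapsed minutes); *output* nodes are the final determinations (overdose,
underdose, delay severity).  Backward chaining from an output node selects
exactly the ancestor subgraph needed to evaluate it, in a deterministic
topological order.

This is deliberately *not* an OWL/RDF ontology: no description logic, no
open-world reasoning — just a typed DAG with rule bindings, which is what
guideline arithmetic needs and what clinicians can audit line by line.
"""
from __future__ import annotations

import heapq
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Optional

import networkx as nx
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

NodeKind = Literal["input", "derived", "output"]
ValueKind = Literal["number", "quantity", "timestamp", "boolean", "categorical"]

SCHEMA_VERSION = "1"

__all__ = [
    "OntologyError",
    "ValueSpec",
    "ConceptNode",
    "Ontology",
    "load_ontology",
    "backward_chain",
    "required_inputs",
    "bundled_ontology",
]


class OntologyError(ValueError):
    """Raised when an ontology document fails validation.

    ``problems`` enumerates every violation found (offending node ids,
    a named cycle, unresolved references) rather than stopping at the first.
    """

    def __init__(self, message: str, problems: Optional[list[str]] = None):
        super().__init__(message)
        self.problems: list[str] = problems or [message]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.problems and self.problems != [base]:
            return base + "\n  - " + "\n  - ".join(self.problems)
        return base


class ValueSpec(BaseModel):
    """Declared type of a node's value.

    Quantities carry an explicit unit (``mg``, ``kg``, ``min``) so the engine
    never compares numbers across units; categorical nodes declare their full
    level set.
    """

    type: ValueKind
    unit: Optional[str] = None
    levels: Optional[list[str]] = None

    @model_validator(mode="after")
    def _check(self) -> "ValueSpec":
        if self.type == "quantity" and not self.unit:
            raise ValueError("quantity nodes must declare a unit")
        if self.type == "categorical" and not self.levels:
            raise ValueError("categorical nodes must declare their level set")
        if self.type != "quantity" and self.unit is not None:
            raise ValueError("only quantity nodes may declare a unit")
        if self.type != "categorical" and self.levels is not None:
            raise ValueError("only categorical nodes may declare levels")
        return self


class ConceptNode(BaseModel):
    node_id: str = Field(min_length=1)
    kind: NodeKind
    value_type: ValueSpec
    description: str = ""
    extraction_hint: Optional[str] = None
    rule_ref: Optional[str] = None
    depends_on: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "ConceptNode":
        if self.kind == "input":
            if self.depends_on:
                raise ValueError(f"input node {self.node_id!r} must not depend on other nodes")
            if self.rule_ref:
                raise ValueError(f"input node {self.node_id!r} must not bind a rule")
        else:
            if not self.depends_on:
                raise ValueError(f"{self.kind} node {self.node_id!r} must have dependencies")
            if not self.rule_ref:
                raise ValueError(f"{self.kind} node {self.node_id!r} must bind a rule")
            if self.extraction_hint:
                raise ValueError(f"{self.kind} node {self.node_id!r} must not carry an extraction hint")
        if len(set(self.depends_on)) != len(self.depends_on):
            raise ValueError(f"node {self.node_id!r} lists a duplicate dependency")
        return self


class Ontology(BaseModel):
    """A named, versioned collection of concept nodes forming a DAG."""

    name: str
    version: str = "1.0"
    nodes: dict[str, ConceptNode]

    @model_validator(mode="after")
    def _validate_graph(self) -> "Ontology":
        problems: list[str] = []
        for key, node in self.nodes.items():
            if key != node.node_id:
                problems.append(f"node keyed {key!r} declares node_id {node.node_id!r}")
            for dep in node.depends_on:
                if dep not in self.nodes:
                    problems.append(f"node {node.node_id!r} depends on unknown node {dep!r}")
        if problems:
            raise OntologyError("unresolved references in ontology", problems)

        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"dependency cycle: {path}", [f"cycle: {path}"])

        if not any(n.kind == "output" for n in self.nodes.values()):
            raise OntologyError("ontology declares no output node")
        return self

    def graph(self) -> nx.DiGraph:
        """Dependency digraph with edges dependency -> dependent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for dep in node.depends_on:
                g.add_edge(dep, node.node_id)
        return g

    @property
    def input_nodes(self) -> list[ConceptNode]:
        return [n for n in self.nodes.values() if n.kind == "input"]

    @property
    def output_nodes(self) -> list[ConceptNode]:
        return [n for n in self.nodes.values() if n.kind == "output"]

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "version": self.version,
            "nodes": {},
        }
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            entry: dict[str, Any] = {
                "kind": node.kind,
                "value_type": node.value_type.model_dump(exclude_none=True),
            }
            if node.description:
                entry["description"] = node.description
            if node.extraction_hint:
                entry["extraction_hint"] = node.extraction_hint
            if node.rule_ref:
                entry["rule_ref"] = node.rule_ref
            if node.depends_on:
                entry["depends_on"] = list(node.depends_on)
            doc["nodes"][nid] = entry
        return doc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _from_document(doc: dict[str, Any]) -> Ontology:
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise OntologyError("ontology document must be a mapping with a 'nodes' section")
    nodes: dict[str, ConceptNode] = {}
    problems: list[str] = []
    for nid, entry in doc["nodes"].items():
        try:
            nodes[nid] = ConceptNode(node_id=nid, **entry)
        except Exception as exc:  # pydantic ValidationError or ValueError
            problems.append(f"{nid}: {exc}")
    if problems:
        raise OntologyError("invalid node definitions", problems)
    try:
        return Ontology(
            name=doc.get("name", "unnamed"),
            version=str(doc.get("version", "1.0")),
            nodes=nodes,
        )
    except ValidationError as exc:
        # unwrap graph-level problems raised inside the pydantic validator
        msgs = [e["msg"].removeprefix("Value error, ") for e in exc.errors()]
        raise OntologyError(msgs[0].splitlines()[0], msgs) from None


def load_ontology(source: str | Path | dict[str, Any]) -> Ontology:
    """Load and validate an ontology from a YAML/JSON file path or a dict.

    Validation failures are enumerated in :class:`OntologyError.problems`;
    a cyclic dependency is reported with one named cycle.
    """
    if isinstance(source, dict):
        return _from_document(source)
    text = Path(source).read_text()
    return _from_document(yaml.safe_load(text))


def _ancestors(onto: Ontology, target: str) -> set[str]:
    """All nodes target transitively depends on (excluding target)."""
    seen: set[str] = set()
    stack = list(onto.nodes[target].depends_on)
    while stack:
        nid = stack.pop()
        if nid not in seen:
            seen.add(nid)
            stack.extend(onto.nodes[nid].depends_on)
    return seen


def backward_chain(onto: Ontology, target: str) -> list[str]:
    """Nodes required to evaluate ``target``, in evaluation order.

    Returns exactly the ancestors of ``target`` plus ``target`` itself in a
    topological order (every node after all its dependencies).  Ties among
    simultaneously-ready nodes break lexicographically by node id, so traces
    are identical across runs and platforms.
    """
    if target not in onto.nodes:
        raise KeyError(f"unknown target node {target!r}")
    subset = _ancestors(onto, target) | {target}
    # Kahn's algorithm restricted to the ancestor subgraph, min-heap tie-break.
    indeg = {nid: sum(1 for d in onto.nodes[nid].depends_on if d in subset) for nid in subset}
    ready = [nid for nid, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[str] = []
    dependents: dict[str, list[str]] = {nid: [] for nid in subset}
    for nid in subset:
        for dep in onto.nodes[nid].depends_on:
            if dep in subset:
                dependents[dep].append(nid)
    while ready:
        nid = heapq.heappop(ready)
        order.append(nid)
        for child in dependents[nid]:
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(ready, child)
    assert len(order) == len(subset)  # acyclicity guaranteed by validation
    return order


def required_inputs(onto: Ontology, target: str) -> set[str]:
    """Input-kind subset of the backward-chained subgraph of ``target``."""
    return {nid for nid in backward_chain(onto, target) if onto.nodes[nid].kind == "input"}


def bundled_ontology() -> Ontology:
    """The packaged epinephrine adverse-safety-event ontology."""
    ref = resources.files("emsafe").joinpath("data/epinephrine.yaml")
    return _from_document(yaml.safe_load(ref.read_text()))
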