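from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from emsafe import bundled_ontology, bundled_registry
from emsafe.ontology import Ontology


@pytest.fixture(scope="session")
def onto():
    return bundled_ontology()


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


T0 = datetime(2026, 3, 15, 10, 0, 0, tzinfo=timezone.utc)


def make_chart_record(
    chart_id="CH001",
    weight_kg=12.0,
    age_years=3,
    arrival=T0,
    arrest=None,
    doses=((0.12, 3.0),),  # (dose_mg, minutes after arrival)
    narrative="",
):
    """Build a chart document dict; arrest defaults to 2 min before arrival."""
    arrest = arrest if arrest is not None else arrival - timedelta(minutes=2)
    return {
        "chart_id": chart_id,
        "patient": {"age_years": age_years, "weight_kg": weight_kg},
        "times": {"unit_arrival": arrival.isoformat(), "arrest_onset": arrest.isoformat()},
        "medications": [
            {"name": "epinephrine", "dose": d, "unit": "mg", "route": "IV",
             "time": (arrival + timedelta(minutes=m)).isoformat()}
            for d, m in doses
        ],
        "narrative": narrative,
    }


def random_dag_ontology(rng: np.random.Generator, max_nodes: int = 12) -> Ontology:
    """Random small DAG with valid node kinds, for graph-algorithm oracles."""
    n = int(rng.integers(2, max_nodes + 1))
    ids = [f"n{i:02d}" for i in range(n)]
    deps: dict[str, list[str]] = {}
    for i, nid in enumerate(ids):
        deps[nid] = [ids[j] for j in range(i) if rng.random() < 0.35]
    if not any(deps.values()):
        deps[ids[-1]] = [ids[0]]
    nodes = {}
    derived = [nid for nid in ids if deps[nid]]
    output = derived[-1]
    for nid in ids:
        if not deps[nid]:
            nodes[nid] = {"kind": "input", "value_type": {"type": "number"}}
        else:
            nodes[nid] = {
                "kind": "output" if nid == output else "derived",
                "value_type": {"type": "number"},
                "rule_ref": f"r_{nid}",
                "depends_on": deps[nid],
            }
    from emsafe.ontology import load_ontology

    return load_ontology({"name": "random", "version": "1", "nodes": nodes})


def brute_force_ancestors(onto: Ontology, target: str) -> set[str]:
    """Transitive-closure oracle over the explicit adjacency lists."""
    closure = {target}
    changed = True
    while changed:
        changed = False
        for nid in list(closure):
            for dep in onto.nodes[nid].depends_on:
                if dep not in closure:
                    closure.add(dep)
                    changed = True
    return closure
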