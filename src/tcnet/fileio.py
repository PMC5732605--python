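"""File formats: the network JSON dialect and the wide trajectory CSV.

Network documents:

    {
      "states": [{"id": "X1", "speed": 0.5, "clamped": false,
                  "combiner": {"family": "ssum", "params": {"lam": "dynamic"}}}, ...],
      "connections": [{"source": "X1", "target": "X2",
                       "weight": 0.3, "adaptive": true}, ...],
      "adaptation": [{"principle": "homophily", "pairs": "all",
                      "alpha": 20, "tau": 0.025, "eta": 0.3}, ...]
    }

Serialisation is canonical (fixed key order, declaration order preserved), so
serialize -> parse -> serialize round-trips byte-identically.

Trajectories are wide CSV: column ``t`` then one column per state id, with
reified weight columns named ``W[src->tgt]``; numbers carry 12 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .combinations import CombinationFunctionSpec
from .engine import Trajectory
from .errors import ParseError, SchemaError
from .model import NetworkSpec, build_network

__all__ = [
    "network_to_document",
    "write_network",
    "read_network",
    "network_to_json",
    "write_trajectory",
    "read_trajectory",
]


def _combiner_doc(spec: CombinationFunctionSpec) -> dict:
    params = {}
    for key in sorted(spec.params):
        v = spec.params[key]
        if isinstance(v, CombinationFunctionSpec):
            v = _combiner_doc(v)
        elif key == "flags":
            v = [bool(f) for f in v]
        elif key == "mu":
            items = v.items() if hasattr(v, "items") else ((p[:2], p[2]) for p in v)
            v = sorted([int(i), int(j), float(c)] for (i, j), c in items)
        params[key] = v
    return {"family": spec.family, "params": params}


def network_to_document(net: NetworkSpec) -> dict:
    """Plain-dict form of a network spec, with canonical key ordering."""
    states = []
    for s in net.states:
        doc = {"id": s.id, "speed": s.speed, "clamped": s.clamped}
        if s.combiner is not None:
            doc["combiner"] = _combiner_doc(s.combiner)
        states.append(doc)
    connections = [
        {"source": c.source, "target": c.target, "weight": c.weight, "adaptive": c.adaptive}
        for c in net.connections
    ]
    adaptation = []
    for block in net.adaptation:
        doc = {"principle": block.principle}
        doc["pairs"] = (
            "all" if block.pairs == "all" else [[s, t] for s, t in block.pairs]
        )
        for key in sorted(block.params):
            v = block.params[key]
            if isinstance(v, CombinationFunctionSpec):
                v = _combiner_doc(v)
            doc[key] = v
        adaptation.append(doc)
    doc = {"states": states, "connections": connections}
    if adaptation:
        doc["adaptation"] = adaptation
    return doc


def network_to_json(net: NetworkSpec) -> str:
    return json.dumps(network_to_document(net), indent=2) + "\n"


def write_network(net: NetworkSpec, path: str | Path) -> None:
    Path(path).write_text(network_to_json(net))


def read_network(path: str | Path) -> NetworkSpec:
    """Parse and validate a network JSON file."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    try:
        return build_network(doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed network document: {exc}") from exc
    except SchemaError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as wide CSV with 12 significant digits."""
    with open(path, "w") as fh:
        fh.write(",".join(["t", *traj.columns]) + "\n")
        for t, row in zip(traj.times, traj.data):
            fh.write(",".join(f"{v:.12g}" for v in (t, *row)) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a wide trajectory CSV (column ``t`` plus one column per state)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if not header or header[0] != "t":
        raise ParseError(f"{path}: first trajectory column must be 't', got {header[:1]}")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate state columns {sorted(dupes)!r}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: malformed trajectory CSV: {exc}") from exc
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: missing or non-numeric field near line {bad}")
    return Trajectory(
        times=frame["t"].to_numpy(),
        columns=tuple(header[1:]),
        data=frame[header[1:]].to_numpy(),
    )
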