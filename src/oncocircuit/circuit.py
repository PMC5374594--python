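"""Combinational netlist model and evaluation.

A signaling network is represented as a purely combinational logic circuit:
named primary inputs (ligands, hormones, tumor suppressors), logic gates
(regulatory relationships), and named primary outputs (proliferation
markers).  Three kinds of annotation decorate the wiring:

* **fault sites** -- numbered lines that may be stuck at a fixed value,
  abstracting oncogenic lesions (stuck-at-1: constitutive activation;
  stuck-at-0: loss of a suppressor);
* **drug points** -- targeted inhibitors modeled as an AND gate with an
  inverted drug input on the target line, so an applied drug forces its
  target to 0;
* the ordering of inputs, outputs and drugs, which fixes the printed
  orientation of all bit vectors.

Line semantics
--------------
Every primary input and every gate output is a *line*, addressed by the
input name or gate id.  The value seen by downstream consumers is computed
in this order:

1. raw value (input bit, or gate function of upstream line values);
2. ``pre_drug`` stuck-at faults override the raw value;
3. each drug point on the line ANDs in the negated drug bit;
4. ``post_drug`` stuck-at faults override the drugged value.

A ``pre_drug`` fault is therefore rectifiable by a drug on the same line,
while a ``post_drug`` fault is immune to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GATE_KINDS",
    "Gate",
    "FaultSite",
    "DrugPoint",
    "Circuit",
    "CircuitError",
    "NetlistSchemaError",
    "NetlistStructureError",
    "load_circuit",
    "loads_circuit",
    "dump_circuit",
    "evaluate",
    "evaluate_streams",
    "hamming_weight",
]

GATE_KINDS = ("AND", "OR", "NOT", "NAND", "NOR", "XOR", "BUF")

PRE_DRUG = "pre_drug"
POST_DRUG = "post_drug"


class CircuitError(ValueError):
    """Base class for netlist errors."""


class NetlistSchemaError(CircuitError):
    """The document does not conform to the netlist schema."""


class NetlistStructureError(CircuitError):
    """The netlist is schema-valid but structurally inconsistent
    (dangling reference, feedback cycle, bad fault labels, ...)."""


@dataclass(frozen=True)
class Gate:
    """A logic gate.

    ``inverted_inputs`` holds 0-based positions of inputs negated before
    the gate function is applied; this expresses inhibiting edges without
    inserting explicit inverters.
    """

    id: str
    kind: str
    inputs: tuple[str, ...]
    inverted_inputs: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise NetlistSchemaError(
                f"gate {self.id!r}: unknown kind {self.kind!r}")
        arity = len(self.inputs)
        if self.kind in ("NOT", "BUF"):
            if arity != 1:
                raise NetlistSchemaError(
                    f"gate {self.id!r}: {self.kind} takes exactly one input")
        elif arity < 2:
            raise NetlistSchemaError(
                f"gate {self.id!r}: {self.kind} needs at least two inputs")
        if not self.inverted_inputs <= set(range(arity)):
            raise NetlistSchemaError(
                f"gate {self.id!r}: inverted_inputs out of range")


@dataclass(frozen=True)
class FaultSite:
    """A numbered potential lesion: ``line`` stuck at ``stuck``.

    ``position`` states whether the stuck value is applied before or after
    any drug gate on the same line.
    """

    label: int
    line: str
    stuck: int
    position: str = PRE_DRUG

    def __post_init__(self) -> None:
        if self.stuck not in (0, 1):
            raise NetlistSchemaError(
                f"fault site {self.label}: stuck value must be 0 or 1")
        if self.position not in (PRE_DRUG, POST_DRUG):
            raise NetlistSchemaError(
                f"fault site {self.label}: bad position {self.position!r}")


@dataclass(frozen=True)
class DrugPoint:
    """A targeted inhibitor acting on one line.

    When drug bit ``index`` is set, the effective line value becomes
    ``line AND NOT drug`` -- the targeted gene product is switched off.
    One drug may gate several lines (e.g. a pan-ERBB inhibitor).
    """

    index: int
    name: str
    target: str

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 6:
            raise NetlistSchemaError(
                f"drug {self.name!r}: index {self.index} outside 0..6")


@dataclass(frozen=True)
class Circuit:
    """A validated combinational netlist.

    Construction performs full structural validation; a ``Circuit`` that
    exists is well-formed (acyclic, fully referenced, labels contiguous).
    """

    name: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    gates: tuple[Gate, ...]
    fault_sites: tuple[FaultSite, ...] = ()
    drug_points: tuple[DrugPoint, ...] = ()
    # caches filled in __post_init__ (not part of equality)
    _topo: tuple[str, ...] = field(
        default=(), compare=False, repr=False)
    _gate_map: Mapping[str, Gate] = field(
        default_factory=dict, compare=False, repr=False)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    @property
    def n_fault_sites(self) -> int:
        return len(self.fault_sites)

    @property
    def n_drugs(self) -> int:
        """Number of distinct drugs (drug-vector length)."""
        if not self.drug_points:
            return 0
        return max(d.index for d in self.drug_points) + 1

    def site(self, label: int) -> FaultSite:
        for s in self.fault_sites:
            if s.label == label:
                return s
        raise KeyError(f"no fault site labeled {label}")

    def topological_order(self) -> tuple[str, ...]:
        """Gate ids in a valid evaluation order."""
        return self._topo

    def __post_init__(self) -> None:
        if len(set(self.inputs)) != len(self.inputs):
            raise NetlistStructureError("duplicate primary input names")
        if len(set(self.outputs)) != len(self.outputs):
            raise NetlistStructureError("duplicate primary output names")
        gate_ids = [g.id for g in self.gates]
        if len(set(gate_ids)) != len(gate_ids):
            dup = sorted({g for g in gate_ids if gate_ids.count(g) > 1})
            raise NetlistStructureError(f"duplicate gate ids: {dup}")
        clash = set(gate_ids) & set(self.inputs)
        if clash:
            raise NetlistStructureError(
                f"gate ids clash with input names: {sorted(clash)}")
        lines = set(self.inputs) | set(gate_ids)
        for g in self.gates:
            for ref in g.inputs:
                if ref not in lines:
                    raise NetlistStructureError(
                        f"gate {g.id!r} references missing line {ref!r}")
        for out in self.outputs:
            if out not in lines:
                raise NetlistStructureError(
                    f"primary output {out!r} is not a line")
        for s in self.fault_sites:
            if s.line not in lines:
                raise NetlistStructureError(
                    f"fault site {s.label} on missing line {s.line!r}")
        labels = sorted(s.label for s in self.fault_sites)
        if labels != list(range(1, len(labels) + 1)):
            raise NetlistStructureError(
                "fault labels must be unique and contiguous 1..P, "
                f"got {labels}")
        for d in self.drug_points:
            if d.target not in lines:
                raise NetlistStructureError(
                    f"drug {d.name!r} targets missing line {d.target!r}")
        # acyclicity + evaluation order
        graph = nx.DiGraph()
        graph.add_nodes_from(gate_ids)
        for g in self.gates:
            for ref in g.inputs:
                if ref in set(gate_ids):
                    graph.add_edge(ref, g.id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise NetlistStructureError(
                f"feedback loop detected: {[e[0] for e in cycle]}")
        object.__setattr__(
            self, "_topo", tuple(nx.lexicographical_topological_sort(graph)))
        object.__setattr__(self, "_gate_map", {g.id: g for g in self.gates})


# ---------------------------------------------------------------------------
# serialization

def _circuit_from_dict(doc: dict, source: str = "<dict>") -> Circuit:
    if not isinstance(doc, dict):
        raise NetlistSchemaError(f"{source}: netlist must be a JSON object")
    required = ("name", "inputs", "outputs", "gates")
    for key in required:
        if key not in doc:
            raise NetlistSchemaError(f"{source}: missing key {key!r}")
    gates = []
    for i, g in enumerate(doc["gates"]):
        try:
            gates.append(Gate(
                id=g["id"], kind=g["kind"], inputs=tuple(g["inputs"]),
                inverted_inputs=frozenset(g.get("inverted_inputs", ()))))
        except (KeyError, TypeError) as exc:
            raise NetlistSchemaError(
                f"{source}: malformed gate entry #{i}: {exc}") from exc
    sites = []
    for i, s in enumerate(doc.get("fault_sites", ())):
        try:
            sites.append(FaultSite(
                label=s["label"], line=s["line"], stuck=s["stuck"],
                position=s.get("position", PRE_DRUG)))
        except (KeyError, TypeError) as exc:
            raise NetlistSchemaError(
                f"{source}: malformed fault_sites entry #{i}: {exc}") from exc
    drugs = []
    for i, d in enumerate(doc.get("drugs", ())):
        try:
            drugs.append(DrugPoint(
                index=d["index"], name=d["name"], target=d["target"]))
        except (KeyError, TypeError) as exc:
            raise NetlistSchemaError(
                f"{source}: malformed drugs entry #{i}: {exc}") from exc
    return Circuit(
        name=doc["name"],
        inputs=tuple(doc["inputs"]),
        outputs=tuple(doc["outputs"]),
        gates=tuple(gates),
        fault_sites=tuple(sites),
        drug_points=tuple(drugs),
    )


def loads_circuit(text: str, source: str = "<string>") -> Circuit:
    """Parse and validate a netlist from a JSON string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetlistSchemaError(f"{source}: invalid JSON: {exc}") from exc
    return _circuit_from_dict(doc, source)


def load_circuit(path: str | Path) -> Circuit:
    """Load and validate a netlist from a JSON file.

    Raises :class:`NetlistSchemaError` for documents that do not match the
    netlist schema and :class:`NetlistStructureError` for well-formed
    documents describing an inconsistent circuit (dangling line references,
    feedback cycles, non-contiguous fault labels).
    """
    path = Path(path)
    return loads_circuit(path.read_text(), source=str(path))


def dump_circuit(circuit: Circuit) -> dict:
    """Serialize a circuit to the JSON netlist dialect (inverse of load)."""
    return {
        "name": circuit.name,
        "inputs": list(circuit.inputs),
        "outputs": list(circuit.outputs),
        "gates": [
            {"id": g.id, "kind": g.kind, "inputs": list(g.inputs),
             "inverted_inputs": sorted(g.inverted_inputs)}
            for g in circuit.gates],
        "fault_sites": [
            {"label": s.label, "line": s.line, "stuck": s.stuck,
             "position": s.position}
            for s in circuit.fault_sites],
        "drugs": [
            {"index": d.index, "name": d.name, "target": d.target}
            for d in circuit.drug_points],
    }


# ---------------------------------------------------------------------------
# evaluation

def hamming_weight(bits: Iterable[int]) -> int:
    """Number of ones; for binary vectors this equals the L1 norm and,
    for output vectors, the count of active proliferative markers."""
    return int(sum(int(b) for b in bits))


def _fault_plan(circuit: Circuit, fault):
    """Map line -> {position: stuck} for the lesions in ``fault``.

    ``fault`` may be ``None``, an iterable of site labels, or any object
    with a ``labels`` attribute (a ``FaultAssignment``).
    """
    if fault is None:
        return {}
    labels = getattr(fault, "labels", fault)
    plan: dict[str, dict[str, int]] = {}
    for label in labels:
        site = circuit.site(int(label))
        slot = plan.setdefault(site.line, {})
        if slot.get(site.position, site.stuck) != site.stuck:
            raise CircuitError(
                f"contradictory lesions at the {site.position} slot of "
                f"line {site.line!r}")
        slot[site.position] = site.stuck
    return plan


def _drug_plan(circuit: Circuit):
    plan: dict[str, list[int]] = {}
    for d in circuit.drug_points:
        plan.setdefault(d.target, []).append(d.index)
    return plan


_GATE_FUNCS = {
    "AND": lambda vals: int(all(vals)),
    "OR": lambda vals: int(any(vals)),
    "NOT": lambda vals: 1 - vals[0],
    "BUF": lambda vals: vals[0],
    "NAND": lambda vals: 1 - int(all(vals)),
    "NOR": lambda vals: 1 - int(any(vals)),
    "XOR": lambda vals: int(sum(vals) % 2),
}


def evaluate(circuit: Circuit,
             x: Sequence[int],
             d: Sequence[int] | None = None,
             fault=None) -> tuple[int, ...]:
    """Evaluate the circuit on one input vector.

    Parameters
    ----------
    x : binary vector of length N (circuit input order)
    d : binary drug vector (length = number of drugs; all-zero if omitted)
    fault : fault assignment (``None``, iterable of site labels, or a
        :class:`~oncocircuit.faults.FaultAssignment`)

    Returns the M-component output vector, gates evaluated in topological
    order with the line semantics described in the module docstring.
    """
    if len(x) != circuit.n_inputs:
        raise CircuitError(
            f"input vector has length {len(x)}, expected {circuit.n_inputs}")
    n_drugs = circuit.n_drugs
    if d is None:
        d = (0,) * max(n_drugs, 1)
    elif n_drugs and len(d) < n_drugs:
        raise CircuitError(
            f"drug vector has length {len(d)}, expected >= {n_drugs}")
    faults = _fault_plan(circuit, fault)
    drugs = _drug_plan(circuit)

    def settle(line: str, value: int) -> int:
        slot = faults.get(line)
        if slot is not None and PRE_DRUG in slot:
            value = slot[PRE_DRUG]
        for idx in drugs.get(line, ()):
            value &= 1 - int(d[idx])
        if slot is not None and POST_DRUG in slot:
            value = slot[POST_DRUG]
        return value

    values: dict[str, int] = {}
    for name, bit in zip(circuit.inputs, x):
        values[name] = settle(name, int(bit))
    gate_map = circuit._gate_map
    for gid in circuit.topological_order():
        gate = gate_map[gid]
        vals = [values[ref] for ref in gate.inputs]
        for pos in gate.inverted_inputs:
            vals[pos] = 1 - vals[pos]
        values[gid] = settle(gid, _GATE_FUNCS[gate.kind](vals))
    return tuple(values[out] for out in circuit.outputs)


# vectorized gate functions for streams (uint8 arrays)

def _reduce_and(vals):
    acc = vals[0]
    for v in vals[1:]:
        acc = acc & v
    return acc


def _reduce_or(vals):
    acc = vals[0]
    for v in vals[1:]:
        acc = acc | v
    return acc


_STREAM_FUNCS = {
    "AND": _reduce_and,
    "OR": _reduce_or,
    "NOT": lambda vals: vals[0] ^ 1,
    "BUF": lambda vals: vals[0],
    "NAND": lambda vals: _reduce_and(vals) ^ 1,
    "NOR": lambda vals: _reduce_or(vals) ^ 1,
    "XOR": lambda vals: np.bitwise_xor.reduce(np.stack(vals), axis=0),
}


def evaluate_streams(circuit: Circuit,
                     X: np.ndarray,
                     d: Sequence[int] | None = None,
                     fault=None) -> np.ndarray:
    """Propagate bitstreams through the circuit.

    ``X`` is an (L, N) binary array: one length-L stream per primary input.
    Returns an (L, M) array, bitwise identical to calling :func:`evaluate`
    on every row.  This is the vectorized propagation engine used by
    stochastic-logic analysis; it shares no code with :func:`evaluate`.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != circuit.n_inputs:
        raise CircuitError(
            f"stream matrix has shape {X.shape}, expected (L, "
            f"{circuit.n_inputs})")
    X = X.astype(np.uint8, copy=False)
    L = X.shape[0]
    n_drugs = circuit.n_drugs
    if d is None:
        d = (0,) * max(n_drugs, 1)
    elif n_drugs and len(d) < n_drugs:
        raise CircuitError(
            f"drug vector has length {len(d)}, expected >= {n_drugs}")
    faults = _fault_plan(circuit, fault)
    drugs = _drug_plan(circuit)

    def settle(line: str, value: np.ndarray) -> np.ndarray:
        slot = faults.get(line)
        if slot is not None and PRE_DRUG in slot:
            value = np.full(L, slot[PRE_DRUG], dtype=np.uint8)
        for idx in drugs.get(line, ()):
            if d[idx]:
                value = np.zeros(L, dtype=np.uint8)
        if slot is not None and POST_DRUG in slot:
            value = np.full(L, slot[POST_DRUG], dtype=np.uint8)
        return value

    values: dict[str, np.ndarray] = {}
    for j, name in enumerate(circuit.inputs):
        values[name] = settle(name, X[:, j])
    gate_map = circuit._gate_map
    for gid in circuit.topological_order():
        gate = gate_map[gid]
        vals = [values[ref] for ref in gate.inputs]
        for pos in gate.inverted_inputs:
            vals[pos] = vals[pos] ^ 1
        values[gid] = settle(gid, _STREAM_FUNCS[gate.kind](vals))
    return np.column_stack([values[out] for out in circuit.outputs])
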