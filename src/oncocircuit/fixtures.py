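"""Synthetic circuits for testing.

The generator draws shallow random combinational circuits (gates may only
read earlier lines, guaranteeing acyclicity by construction) with
annotated fault sites and drug points, so every analysis in this package
can be exercised — and cross-checked against exhaustive oracles — without
the bundled reference model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit, CircuitError, DrugPoint, FaultSite, Gate, \
    GATE_KINDS

__all__ = ["FixtureSpec", "random_circuit", "toy_stuck_nand"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random circuit draw.

    ``fault_density`` / ``drug_density`` are the per-line probabilities of
    annotating a fault site / attaching a drug point (drug indices cycle
    through 0..6).  ``gate_kinds`` restricts the drawn kinds; fan-in for
    multi-input kinds is 2 or 3.
    """

    n_inputs: int = 4
    n_gates: int = 8
    n_outputs: int = 2
    gate_kinds: tuple[str, ...] = GATE_KINDS
    fault_density: float = 0.4
    drug_density: float = 0.2
    invert_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_gates < 1 or self.n_outputs < 1:
            raise CircuitError("fixture needs >=1 input, gate and output")
        if self.n_outputs > self.n_inputs + self.n_gates:
            raise CircuitError("more outputs than lines")
        bad = set(self.gate_kinds) - set(GATE_KINDS)
        if bad:
            raise CircuitError(f"unknown gate kinds: {sorted(bad)}")


def random_circuit(spec: FixtureSpec) -> Circuit:
    """Draw a random valid circuit; the same spec yields the same circuit."""
    rng = np.random.default_rng(spec.seed)
    inputs = tuple(f"x{i}" for i in range(spec.n_inputs))
    lines: list[str] = list(inputs)
    gates: list[Gate] = []
    for gi in range(spec.n_gates):
        kind = str(rng.choice(spec.gate_kinds))
        if kind in ("NOT", "BUF"):
            fan_in = 1
        else:
            fan_in = int(rng.integers(2, 4))
        fan_in = min(fan_in, len(lines))
        if fan_in < 2 and kind not in ("NOT", "BUF"):
            kind = "BUF"
            fan_in = 1
        picks = tuple(str(s) for s in
                      rng.choice(lines, size=fan_in, replace=False))
        inverted = frozenset(
            int(i) for i in range(fan_in)
            if rng.random() < spec.invert_prob)
        gid = f"g{gi}"
        gates.append(Gate(gid, kind, picks, inverted))
        lines.append(gid)
    # outputs: prefer late lines so most of the circuit is observable
    out_pool = list(reversed(lines))[:max(spec.n_outputs * 2,
                                          spec.n_outputs)]
    outputs = tuple(str(s) for s in rng.choice(
        out_pool, size=spec.n_outputs, replace=False))
    sites: list[FaultSite] = []
    for line in lines:
        if rng.random() < spec.fault_density:
            sites.append(FaultSite(
                label=len(sites) + 1, line=line,
                stuck=int(rng.integers(0, 2))))
    drugs: list[DrugPoint] = []
    for line in lines:
        if rng.random() < spec.drug_density:
            idx = len(drugs) % 7
            drugs.append(DrugPoint(index=idx, name=f"drug{idx}",
                                   target=line))
    return Circuit(
        name=f"random-{spec.seed}",
        inputs=inputs,
        outputs=outputs,
        gates=tuple(gates),
        fault_sites=tuple(sites),
        drug_points=tuple(drugs),
    )


def toy_stuck_nand() -> Circuit:
    """A four-input teaching circuit for stuck-at semantics.

    ``OR(NAND(a, b), AND(c, d))``: on input <abcd> = 1100 the output is 0,
    but with the annotated stuck-at-1 fault at the NAND output it becomes
    1.  A drug point on the unrelated AND line shows non-interference.
    """
    return Circuit(
        name="toy-stuck-nand",
        inputs=("a", "b", "c", "d"),
        outputs=("out",),
        gates=(
            Gate("n1", "NAND", ("a", "b")),
            Gate("n2", "AND", ("c", "d")),
            Gate("out", "OR", ("n1", "n2")),
        ),
        fault_sites=(FaultSite(label=1, line="n1", stuck=1),),
        drug_points=(DrugPoint(index=0, name="drug0", target="n2"),),
    )
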