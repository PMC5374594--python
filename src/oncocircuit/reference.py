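"""The bundled CRPC reference model and its constraint-validation harness.

The reference netlist (``data/prostate_crpc.json``) transcribes the
castration-resistant prostate cancer signaling network into gate-level
logic; ``data/TRANSCRIPTION_NOTES.md`` records how the wiring was pinned
down and what freedom remains.  This module carries the fixed printed
orderings (inputs, outputs, drugs), the non-proliferative reference input
x*, the expected benchmark results, and
:func:`validate_reference_network`, which re-derives every benchmark from
a candidate netlist and reports each constraint separately.  The expected
values live here as *validation data*; nothing in the evaluator or the
search code consults them.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

from .circuit import Circuit, evaluate, hamming_weight, loads_circuit
from .faults import FaultAssignment, fault_combinations
from .intervention import bits_to_str, drug_space, optimal_cocktail, \
    therapy_table
from .vulnerability import DEFAULT_SEED, DEFAULT_STREAM_LENGTH, \
    vulnerability_report

__all__ = [
    "INPUT_ORDER",
    "OUTPUT_ORDER",
    "DRUG_ORDER",
    "X_STAR",
    "EXPECTED_THERAPY",
    "EXPECTED_UNTESTABLE",
    "EXPECTED_COCKTAIL",
    "EXPECTED_VULNERABILITY_PERCENT",
    "EXPECTED_VULNERABILITY_EXACT",
    "VULNERABILITY_TOLERANCE",
    "ConstraintCheck",
    "ConstraintReport",
    "load_reference_circuit",
    "reference_netlist_text",
    "validate_reference_network",
]

#: printed component order of the input vector
INPUT_ORDER = ("EGF", "HBEGF", "IGF", "NRG1", "PTEN", "NKX3_1", "Androgens")
#: printed component order of the output vector
OUTPUT_ORDER = ("SP1", "SRF_ELK1", "PSA", "TMPRSS2", "BCL2", "CDK2_CYCLINE")
#: printed component order of the drug vector
DRUG_ORDER = ("Lapatinib", "Cixutumumab", "AZD6244", "BKM120", "AZD5363",
              "Temsirolimus", "Enzalutamide")

#: the non-proliferative input: growth factors and androgens absent, the
#: tumor suppressors PTEN and NKX3.1 active
X_STAR = (0, 0, 0, 0, 1, 1, 0)

#: benchmark best-therapy table: fault label -> canonical drug vector
EXPECTED_THERAPY = {
    1: "1000000", 2: "1000000", 3: "0100000", 4: "1000000",
    5: "0011000", 6: "0011000", 7: "0000100", 8: "0001000", 9: "0001000",
    10: "0000100", 11: "0000100", 12: "0000100", 13: "0000100",
    14: "0000001", 15: "0000001", 16: "0010000", 17: "0010000",
    18: "0000000", 19: "0000010", 20: "0000010", 21: "0000010",
    22: "0000000", 23: "0000000", 24: "0000000",
}

#: faults no drug vector can improve; all are minimally proliferative
#: (weight 1) except fault 18 (weight 2)
EXPECTED_UNTESTABLE = frozenset({18, 22, 23, 24})

#: globally optimal <=3-drug cocktail: AZD6244 + AZD5363 + Enzalutamide
EXPECTED_COCKTAIL = "0010101"

#: benchmark vulnerabilities in percent, as printed (Monte-Carlo estimates
#: at stream length 10^6)
EXPECTED_VULNERABILITY_PERCENT = {
    1: 6.25, 2: 6.25, 3: 6.25, 4: 6.25, 5: 6.25, 6: 6.25,
    7: 24.98, 8: 6.25, 9: 6.25, 10: 24.98, 11: 24.98, 12: 24.98,
    13: 24.98, 14: 12.47, 15: 12.47, 16: 6.25, 17: 6.25, 18: 6.25,
    19: 1.57, 20: 1.57, 21: 1.57, 22: 1.57, 23: 1.57, 24: 24.98,
}

#: the exact rationals behind the printed estimates (denominator 2^7)
EXPECTED_VULNERABILITY_EXACT = {
    label: {6.25: Fraction(1, 16), 24.98: Fraction(1, 4),
            12.47: Fraction(1, 8), 1.57: Fraction(1, 64)}[pct]
    for label, pct in EXPECTED_VULNERABILITY_PERCENT.items()
}

#: absolute tolerance for matching the printed percentages / 100; the
#: printed values sit within Monte-Carlo noise of the exact rationals at
#: stream length 10^6
VULNERABILITY_TOLERANCE = 0.002


def reference_netlist_text() -> str:
    """Raw JSON text of the bundled reference netlist."""
    return (resources.files("oncocircuit") / "data" /
            "prostate_crpc.json").read_text()


def load_reference_circuit() -> Circuit:
    """Load the bundled CRPC reference circuit (N=7, M=6, P=24)."""
    return loads_circuit(reference_netlist_text(), source="prostate_crpc.json")


@dataclass(frozen=True)
class ConstraintCheck:
    """One validated statement: observed versus expected."""

    name: str
    passed: bool
    observed: object
    expected: object

    def __str__(self) -> str:
        flag = "PASS" if self.passed else "FAIL"
        return f"[{flag}] {self.name}: observed={self.observed!r} " \
               f"expected={self.expected!r}"


@dataclass(frozen=True)
class ConstraintReport:
    """Itemized validation outcome; overall pass iff every check passes."""

    checks: tuple[ConstraintCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> tuple[ConstraintCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)

    def __str__(self) -> str:
        lines = [str(c) for c in self.checks]
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def validate_reference_network(circuit: Circuit,
                               length: int = DEFAULT_STREAM_LENGTH,
                               seed: int = DEFAULT_SEED) -> ConstraintReport:
    """Check a candidate reference transcription against every
    machine-checkable benchmark statement.

    Checks, in order: structural counts (N, M, P); the fault-free
    non-proliferative response to x*; all 24 best-therapy rows (full
    128-vector drug space); the untestable set and the weight profile of
    its members; the globally optimal <=3-drug cocktail under <=3
    simultaneous faults; and all 24 stochastic vulnerabilities at the
    given stream length and seed.  Failures are report entries, never
    exceptions, so a mutated or mis-transcribed netlist yields a readable
    diff of which published statements it violates.
    """
    checks: list[ConstraintCheck] = []

    # (a) structural counts
    checks.append(ConstraintCheck(
        "structure N,M,P",
        (circuit.n_inputs, circuit.n_outputs, circuit.n_fault_sites)
        == (7, 6, 24),
        (circuit.n_inputs, circuit.n_outputs, circuit.n_fault_sites),
        (7, 6, 24)))
    if not checks[0].passed:
        return ConstraintReport(tuple(checks))

    # (b) fault-free non-proliferative output
    z0 = evaluate(circuit, X_STAR, None, None)
    checks.append(ConstraintCheck(
        "fault-free output at x* all-zero", hamming_weight(z0) == 0,
        bits_to_str(z0), "000000"))

    # (c) best-therapy table under the full drug space
    full = drug_space(7)
    table = therapy_table(circuit, full, X_STAR)
    for rec in table:
        exp = EXPECTED_THERAPY[rec.fault_label]
        checks.append(ConstraintCheck(
            f"therapy fault {rec.fault_label}", rec.canonical_str == exp,
            rec.canonical_str, exp))

    # (d) untestable set and its weight profile
    untestable = {r.fault_label for r in table if r.untestable}
    checks.append(ConstraintCheck(
        "untestable set", untestable == set(EXPECTED_UNTESTABLE),
        tuple(sorted(untestable)), tuple(sorted(EXPECTED_UNTESTABLE))))
    weights = {r.fault_label: r.achieved_weight
               for r in table if r.untestable}
    expected_weights = {lb: (2 if lb == 18 else 1)
                        for lb in sorted(untestable)}
    checks.append(ConstraintCheck(
        "untestable weights (only fault 18 above 1)",
        weights == expected_weights, weights, expected_weights))

    # (e) optimal cocktail, <=3 drugs x <=3 faults
    cocktail = optimal_cocktail(
        circuit, drug_space(3), fault_combinations(circuit, 3), X_STAR)
    checks.append(ConstraintCheck(
        "optimal cocktail", cocktail.optimal_str == EXPECTED_COCKTAIL,
        cocktail.optimal_str, EXPECTED_COCKTAIL))

    # (f) vulnerabilities
    records = vulnerability_report(circuit, length, seed, exact=False)
    for rec in records:
        exp = EXPECTED_VULNERABILITY_PERCENT[rec.site_label] / 100.0
        ok = abs(rec.v_stochastic - exp) <= VULNERABILITY_TOLERANCE
        checks.append(ConstraintCheck(
            f"vulnerability site {rec.site_label}", ok,
            round(rec.v_stochastic, 5), exp))

    return ConstraintReport(tuple(checks))
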