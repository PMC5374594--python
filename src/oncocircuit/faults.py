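"""Stuck-at fault assignments and bounded fault-combination enumeration.

Each annotated site carries exactly one stuck polarity (the lesion type a
dysfunction of that node produces), so a circuit with P sites has P single
faults, not 2P.  Multi-lesion tumors are modeled as sets of up to ``k_max``
simultaneous lesions; the number of combinations follows the closed form

    C = sum_{k=0}^{k_max} binom(P, k)

including the empty, fault-free assignment f0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

from .circuit import Circuit, CircuitError

__all__ = [
    "FaultAssignment",
    "FaultSpace",
    "single_faults",
    "fault_combinations",
    "fault_space_size",
]


@dataclass(frozen=True)
class FaultAssignment:
    """A set of lesions: (site label, stuck value) pairs.

    The empty assignment is the fault-free case f0.  Lesions are kept
    sorted by label so equal assignments compare equal.
    """

    lesions: tuple[tuple[int, int], ...] = ()

    @classmethod
    def from_labels(cls, circuit: Circuit, labels) -> "FaultAssignment":
        """Build an assignment using each site's annotated stuck value."""
        labels = sorted(set(int(x) for x in labels))
        return cls(tuple((lb, circuit.site(lb).stuck) for lb in labels))

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(lb for lb, _ in self.lesions)

    @property
    def cardinality(self) -> int:
        return len(self.lesions)

    def is_fault_free(self) -> bool:
        return not self.lesions

    def __str__(self) -> str:
        if not self.lesions:
            return "f0"
        return "+".join(f"{lb}sa{v}" for lb, v in self.lesions)


F0 = FaultAssignment()


@dataclass(frozen=True)
class FaultSpace:
    """All fault combinations of cardinality <= ``max_cardinality``,
    deterministically ordered by cardinality then label-lexicographically.
    The first element is always f0."""

    circuit: Circuit
    max_cardinality: int
    combinations: tuple[FaultAssignment, ...]

    @property
    def size(self) -> int:
        return len(self.combinations)

    def __iter__(self):
        return iter(self.combinations)

    def __len__(self) -> int:
        return len(self.combinations)


def fault_space_size(n_sites: int, k_max: int) -> int:
    """Closed-form size of the bounded fault space."""
    return sum(comb(n_sites, k) for k in range(k_max + 1))


def single_faults(circuit: Circuit) -> list[FaultAssignment]:
    """One single-lesion assignment per annotated site, ordered by label."""
    return [FaultAssignment(((s.label, s.stuck),))
            for s in sorted(circuit.fault_sites, key=lambda s: s.label)]


def fault_combinations(circuit: Circuit, k_max: int) -> FaultSpace:
    """Enumerate all fault combinations with at most ``k_max`` lesions.

    Ordering is deterministic: by cardinality, then lexicographically on
    the sorted label tuples, so downstream argmin searches and reports are
    reproducible.
    """
    P = circuit.n_fault_sites
    if not 0 <= k_max <= P:
        raise CircuitError(
            f"k_max must be in 0..{P}, got {k_max}")
    stuck = {s.label: s.stuck for s in circuit.fault_sites}
    labels = sorted(stuck)
    combos: list[FaultAssignment] = []
    for k in range(k_max + 1):
        for subset in itertools.combinations(labels, k):
            combos.append(FaultAssignment(
                tuple((lb, stuck[lb]) for lb in subset)))
    return FaultSpace(circuit, k_max, tuple(combos))
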