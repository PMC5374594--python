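"""Drug-vector spaces and therapy search.

A therapy is a binary drug vector d selecting a subset of the available
targeted inhibitors.  For a fixed non-proliferative input x* the faulty
circuit's output weight ||psi(x*, d, f)||_1 counts the proliferative
markers still active; the best therapy for a fault minimizes that weight,
breaking ties toward fewer drugs (side-effect parsimony) and then toward
the lexicographically smallest bit string (a reporting convention -- all
co-optimal vectors are retained).

The globally optimal cocktail minimizes the *sum* of output weights over
every non-empty fault combination in a bounded fault space:

    d* = argmin_d  sum_{j=1}^{C-1} ||psi(x*, d, f_j)||_1

computed by exhaustive enumeration with exact integer totals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

from .circuit import Circuit, CircuitError, evaluate, hamming_weight
from .faults import FaultAssignment, FaultSpace, single_faults

__all__ = [
    "DrugSpace",
    "TherapyRecord",
    "CocktailResult",
    "drug_space",
    "best_therapy_single_fault",
    "therapy_table",
    "optimal_cocktail",
    "bits_to_str",
]


def bits_to_str(bits: Sequence[int]) -> str:
    """Render a bit vector as a compact string in printed order."""
    return "".join(str(int(b)) for b in bits)


@dataclass(frozen=True)
class DrugSpace:
    """All drug vectors with at most ``max_cardinality`` drugs applied,
    ordered by cardinality then lexicographically; the all-zero vector
    d0 comes first."""

    n_drugs: int
    max_cardinality: int
    vectors: tuple[tuple[int, ...], ...]

    @property
    def size(self) -> int:
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)


def drug_space(max_cardinality: int, n_drugs: int = 7) -> DrugSpace:
    """Enumerate drug vectors with at most ``max_cardinality`` ones.

    ``max_cardinality = n_drugs`` yields the full space of 2**n_drugs
    vectors; the size follows sum_k binom(n_drugs, k).
    """
    if not 0 <= max_cardinality <= n_drugs:
        raise CircuitError(
            f"max_cardinality must be in 0..{n_drugs}, got {max_cardinality}")
    vectors = []
    for k in range(max_cardinality + 1):
        layer = []
        for positions in itertools.combinations(range(n_drugs), k):
            vec = [0] * n_drugs
            for p in positions:
                vec[p] = 1
            layer.append(tuple(vec))
        layer.sort()
        vectors.extend(layer)
    assert len(vectors) == sum(
        comb(n_drugs, k) for k in range(max_cardinality + 1))
    return DrugSpace(n_drugs, max_cardinality, tuple(vectors))


@dataclass(frozen=True)
class TherapyRecord:
    """Best therapy found for one fault.

    ``best_vectors`` lists every co-optimal drug vector (minimal output
    weight, then minimal drug count); ``canonical`` is the
    lexicographically smallest of them.  A fault is *untestable* when no
    drug vector strictly improves on the undrugged faulty output -- the
    best achievable weight equals the undrugged weight and the canonical
    vector is d0.
    """

    fault_label: int
    best_vectors: tuple[tuple[int, ...], ...]
    achieved_weight: int
    undrugged_weight: int

    @property
    def canonical(self) -> tuple[int, ...]:
        return min(self.best_vectors)

    @property
    def untestable(self) -> bool:
        return self.achieved_weight == self.undrugged_weight

    @property
    def canonical_str(self) -> str:
        return bits_to_str(self.canonical)


@dataclass(frozen=True)
class CocktailResult:
    """Outcome of the global search: the optimal vector, its exact total
    weight over all non-empty fault combinations, and the full ranking."""

    optimal_vector: tuple[int, ...]
    total_weight: int
    ranking: tuple[tuple[tuple[int, ...], int], ...]
    n_fault_combinations: int

    @property
    def optimal_str(self) -> str:
        return bits_to_str(self.optimal_vector)

    def drug_names(self, names: Sequence[str]) -> tuple[str, ...]:
        return tuple(n for n, b in zip(names, self.optimal_vector) if b)


def best_therapy_single_fault(circuit: Circuit,
                              fault: FaultAssignment,
                              space: DrugSpace,
                              x: Sequence[int]) -> TherapyRecord:
    """Search ``space`` exhaustively for the best therapy for one fault."""
    if fault.cardinality != 1:
        raise CircuitError("best_therapy_single_fault expects a single-site "
                           f"assignment, got {fault}")
    d0 = (0,) * space.n_drugs
    undrugged = hamming_weight(evaluate(circuit, x, d0, fault))
    weights = [(hamming_weight(evaluate(circuit, x, d, fault)), d)
               for d in space]
    min_w = min(w for w, _ in weights)
    min_card = min(sum(d) for w, d in weights if w == min_w)
    best = tuple(sorted(
        d for w, d in weights if w == min_w and sum(d) == min_card))
    return TherapyRecord(
        fault_label=fault.labels[0],
        best_vectors=best,
        achieved_weight=min_w,
        undrugged_weight=undrugged,
    )


def therapy_table(circuit: Circuit,
                  space: DrugSpace,
                  x: Sequence[int]) -> list[TherapyRecord]:
    """Best therapy for every annotated single fault, ordered by label."""
    return [best_therapy_single_fault(circuit, f, space, x)
            for f in single_faults(circuit)]


def optimal_cocktail(circuit: Circuit,
                     space: DrugSpace,
                     fault_space: FaultSpace,
                     x: Sequence[int]) -> CocktailResult:
    """Exhaustively minimize the total output weight across all non-empty
    fault combinations.

    The fault-free assignment f0 (first element of the fault space) is
    excluded from the sum.  Totals are exact integers; the ranking is
    sorted ascending by (total, drug count, bit string), and the optimal
    vector is the first entry, so ties resolve toward fewer drugs and then
    the lexicographically smallest vector.
    """
    combos = [f for f in fault_space if not f.is_fault_free()]
    totals: list[tuple[tuple[int, ...], int]] = []
    for d in space:
        total = 0
        for f in combos:
            total += hamming_weight(evaluate(circuit, x, d, f))
        totals.append((d, total))
    ranking = tuple(sorted(totals, key=lambda t: (t[1], sum(t[0]), t[0])))
    best_vec, best_total = ranking[0]
    return CocktailResult(
        optimal_vector=best_vec,
        total_weight=best_total,
        ranking=ranking,
        n_fault_combinations=len(combos),
    )
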