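"""Stochastic-logic node vulnerability analysis.

The vulnerability of a node is the probability, over the input
distribution, that the circuit's outputs differ from the fault-free
outputs when that node is dysfunctional (its annotated stuck-at fault is
active); it is the complement of reliability.

Signal probabilities are encoded as bitstreams: a length-L binary
sequence encodes p = (number of ones) / L.  Inputs use *non-Bernoulli*
sequences -- random permutations of a fixed number round(p*L) of ones --
whose marginal frequencies are exact, which removes the input-encoding
component of Monte-Carlo fluctuation.  Each primary input stream is an
independent permutation (independent child seeds spawned from the master
seed), keeping joint input statistics unbiased.

With input stream matrix X (L rows, one per stream position), faulty and
fault-free outputs psi and psi' are compared with the stochastic-logic
comparator architecture: XNOR each output pair, AND across the M
outputs, complement, and decode:

    v = (1/L) * sum_k  NOT( AND_i  psi_i(X_k) XNOR psi_i'(X_k) )

No drugs are applied during vulnerability analysis (d = d0).

An exact counterpart enumerates all 2^N input patterns under uniform
independent inputs (p = 0.5) using the scalar evaluator; the stochastic
and exact paths share no propagation code and serve as mutual oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import Circuit, CircuitError, FaultSite, evaluate, \
    evaluate_streams

__all__ = [
    "StochasticStream",
    "VulnerabilityRecord",
    "non_bernoulli_stream",
    "decode_stream",
    "vulnerability_stochastic",
    "vulnerability_exact",
    "vulnerability_report",
    "DEFAULT_STREAM_LENGTH",
    "DEFAULT_SEED",
]

DEFAULT_STREAM_LENGTH = 1_000_000
DEFAULT_SEED = 17
#: refuse exact enumeration beyond this many primary inputs
EXACT_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class StochasticStream:
    """A binary sequence encoding a probability as its fraction of ones."""

    bits: np.ndarray

    @property
    def length(self) -> int:
        return int(self.bits.shape[0])

    @property
    def encoded_p(self) -> float:
        return float(np.count_nonzero(self.bits)) / self.length


@dataclass(frozen=True)
class VulnerabilityRecord:
    """Vulnerability of one fault site.

    ``v_stochastic`` is the bitstream estimate (None if not computed),
    ``v_exact`` the exhaustive-enumeration value (None if not computed,
    a rational with denominator 2^N otherwise).
    """

    site_label: int
    v_stochastic: float | None = None
    v_exact: float | None = None
    length: int | None = None
    seed: int | None = None


def non_bernoulli_stream(p: float, length: int,
                         seed: int | np.random.Generator) -> StochasticStream:
    """A random permutation of exactly round(p*L) ones and L - round(p*L)
    zeros.  The same seed always yields the identical stream."""
    if not 0.0 <= p <= 1.0:
        raise CircuitError(f"probability must be in [0, 1], got {p}")
    if length < 1:
        raise CircuitError(f"stream length must be >= 1, got {length}")
    ones = int(round(p * length))
    bits = np.zeros(length, dtype=np.uint8)
    bits[:ones] = 1
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rng.shuffle(bits)
    return StochasticStream(bits)


def decode_stream(stream: StochasticStream | np.ndarray) -> float:
    """Decode a bitstream to the probability it encodes: ones / length."""
    bits = stream.bits if isinstance(stream, StochasticStream) else \
        np.asarray(stream)
    if bits.shape[0] < 1:
        raise CircuitError("cannot decode an empty stream")
    return float(np.count_nonzero(bits)) / bits.shape[0]


def _input_streams(circuit: Circuit, length: int, seed: int,
                   p: float = 0.5) -> np.ndarray:
    """(L, N) matrix of mutually independent non-Bernoulli input streams.

    Child seeds are spawned from the master seed with a per-input counter
    so streams are independent but jointly reproducible.
    """
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(circuit.n_inputs)
    cols = [non_bernoulli_stream(p, length, np.random.default_rng(c)).bits
            for c in children]
    return np.column_stack(cols)


def _vulnerability_from_outputs(z_clean: np.ndarray,
                                z_faulty: np.ndarray) -> float:
    """Comparator combine on raw output streams: XNOR, AND across outputs,
    complement, decode."""
    xnor = (z_faulty ^ z_clean) ^ 1
    reliability_stream = np.bitwise_and.reduce(xnor, axis=1)
    vulnerability_stream = reliability_stream ^ 1
    return decode_stream(vulnerability_stream)


def _resolve_site(circuit: Circuit, site: FaultSite | int) -> FaultSite:
    return site if isinstance(site, FaultSite) else circuit.site(int(site))


def vulnerability_stochastic(circuit: Circuit,
                             site: FaultSite | int,
                             length: int = DEFAULT_STREAM_LENGTH,
                             seed: int = DEFAULT_SEED) -> VulnerabilityRecord:
    """Estimate one node's vulnerability from length-L bitstreams.

    Generates N independent non-Bernoulli input streams at p = 0.5,
    propagates them through the fault-free and the faulty circuit (same
    streams, no drugs), and decodes the comparator combine.
    """
    if length < 1:
        raise CircuitError(f"stream length must be >= 1, got {length}")
    site = _resolve_site(circuit, site)
    X = _input_streams(circuit, length, seed)
    z_clean = evaluate_streams(circuit, X, None, None)
    z_faulty = evaluate_streams(circuit, X, None, [site.label])
    v = _vulnerability_from_outputs(z_clean, z_faulty)
    return VulnerabilityRecord(site_label=site.label, v_stochastic=v,
                               length=length, seed=seed)


def vulnerability_exact(circuit: Circuit,
                        site: FaultSite | int) -> VulnerabilityRecord:
    """Exact vulnerability by exhaustive enumeration of all 2^N input
    patterns under independent uniform inputs.

    Uses the scalar evaluator pattern by pattern, independently of the
    vectorized stream engine.  Refuses circuits with more inputs than the
    enumeration cap; use the stochastic estimator there.
    """
    N = circuit.n_inputs
    if N > EXACT_ENUMERATION_CAP:
        raise CircuitError(
            f"{N} inputs exceed the exact-enumeration cap "
            f"({EXACT_ENUMERATION_CAP}); use vulnerability_stochastic")
    site = _resolve_site(circuit, site)
    differing = 0
    for pattern in itertools.product((0, 1), repeat=N):
        if evaluate(circuit, pattern, None, None) != \
                evaluate(circuit, pattern, None, [site.label]):
            differing += 1
    return VulnerabilityRecord(site_label=site.label,
                               v_exact=differing / 2 ** N)


def vulnerability_report(circuit: Circuit,
                         length: int = DEFAULT_STREAM_LENGTH,
                         seed: int = DEFAULT_SEED,
                         exact: bool = True) -> list[VulnerabilityRecord]:
    """Vulnerability of every annotated site, ordered by label.

    The same input stream matrix (hence the same seed) is shared across
    sites, with the fault-free propagation done once.
    """
    if length < 1:
        raise CircuitError(f"stream length must be >= 1, got {length}")
    X = _input_streams(circuit, length, seed)
    z_clean = evaluate_streams(circuit, X, None, None)
    records = []
    for s in sorted(circuit.fault_sites, key=lambda s: s.label):
        z_faulty = evaluate_streams(circuit, X, None, [s.label])
        v_st = _vulnerability_from_outputs(z_clean, z_faulty)
        v_ex = vulnerability_exact(circuit, s).v_exact if exact else None
        records.append(VulnerabilityRecord(
            site_label=s.label, v_stochastic=v_st, v_exact=v_ex,
            length=length, seed=seed))
    return records
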