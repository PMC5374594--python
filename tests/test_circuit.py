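"""Netlist model, loading errors, and scalar/stream evaluation."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oncocircuit import (
    Circuit,
    CircuitError,
    DrugPoint,
    FaultSite,
    FixtureSpec,
    Gate,
    NetlistSchemaError,
    NetlistStructureError,
    dump_circuit,
    evaluate,
    evaluate_streams,
    hamming_weight,
    loads_circuit,
    random_circuit,
)
from oncocircuit.reference import X_STAR


def make_netlist(**overrides):
    doc = {
        "name": "t",
        "inputs": ["a", "b"],
        "outputs": ["g1"],
        "gates": [{"id": "g0", "kind": "AND", "inputs": ["a", "b"]},
                  {"id": "g1", "kind": "NOT", "inputs": ["g0"]}],
    }
    doc.update(overrides)
    return json.dumps(doc)


class TestLoading:
    def test_load_reference_counts(self, reference):
        assert reference.n_inputs == 7
        assert reference.n_outputs == 6
        assert reference.n_fault_sites == 24
        assert reference.n_drugs == 7

    def test_load_from_file(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(make_netlist())
        from oncocircuit import load_circuit
        c = load_circuit(path)
        assert c.name == "t"

    def test_dangling_reference_is_structural_error(self):
        doc = make_netlist(gates=[
            {"id": "g0", "kind": "AND", "inputs": ["a", "missing"]},
            {"id": "g1", "kind": "NOT", "inputs": ["g0"]}])
        with pytest.raises(NetlistStructureError, match="missing"):
            loads_circuit(doc)

    def test_two_gate_feedback_loop_is_cycle_error(self):
        doc = make_netlist(gates=[
            {"id": "g0", "kind": "AND", "inputs": ["a", "g1"]},
            {"id": "g1", "kind": "OR", "inputs": ["g0", "b"]}])
        with pytest.raises(NetlistStructureError, match="feedback"):
            loads_circuit(doc)

    def test_schema_violations_name_the_offender(self):
        with pytest.raises(NetlistSchemaError, match="missing key"):
            loads_circuit(json.dumps({"name": "x"}))
        with pytest.raises(NetlistSchemaError, match="unknown kind"):
            loads_circuit(make_netlist(gates=[
                {"id": "g0", "kind": "XYZZY", "inputs": ["a", "b"]},
                {"id": "g1", "kind": "NOT", "inputs": ["g0"]}]))
        with pytest.raises(NetlistSchemaError, match="exactly one input"):
            Gate("g", "NOT", ("a", "b"))
        with pytest.raises(NetlistSchemaError, match="at least two"):
            Gate("g", "AND", ("a",))

    def test_fault_labels_must_be_contiguous(self):
        doc = json.loads(make_netlist())
        doc["fault_sites"] = [{"label": 2, "line": "g0", "stuck": 1}]
        with pytest.raises(NetlistStructureError, match="contiguous"):
            loads_circuit(json.dumps(doc))

    def test_duplicate_gate_ids_rejected(self):
        doc = make_netlist(gates=[
            {"id": "g0", "kind": "AND", "inputs": ["a", "b"]},
            {"id": "g0", "kind": "OR", "inputs": ["a", "b"]},
            {"id": "g1", "kind": "NOT", "inputs": ["g0"]}])
        with pytest.raises(NetlistStructureError, match="duplicate"):
            loads_circuit(doc)


class TestEvaluate:
    def test_nonproliferative_input_gives_all_zero(self, reference):
        assert evaluate(reference, X_STAR) == (0, 0, 0, 0, 0, 0)

    def test_toy_stuck_nand_example(self, toy):
        x = (1, 1, 0, 0)
        assert evaluate(toy, x) == (0,)
        assert evaluate(toy, x, fault=[1]) == (1,)
        # the drug targets an unrelated line; outputs are unchanged
        assert evaluate(toy, x, (1, 0, 0, 0, 0, 0, 0), [1]) == (1,)

    def test_single_buffer_wire_identity(self):
        c = Circuit("wire", ("a",), ("g",), (Gate("g", "BUF", ("a",)),))
        assert evaluate(c, [1]) == (1,)
        assert evaluate(c, [0]) == (0,)

    def test_dimension_mismatch_is_contract_error(self, toy):
        with pytest.raises(CircuitError, match="length"):
            evaluate(toy, (1, 1, 0))

    def test_gate_kinds_truth_tables(self):
        for kind, fn in [("AND", lambda a, b: a & b),
                         ("OR", lambda a, b: a | b),
                         ("NAND", lambda a, b: 1 - (a & b)),
                         ("NOR", lambda a, b: 1 - (a | b)),
                         ("XOR", lambda a, b: a ^ b)]:
            c = Circuit("t", ("a", "b"), ("g",),
                        (Gate("g", kind, ("a", "b")),))
            for a, b in itertools.product((0, 1), repeat=2):
                assert evaluate(c, (a, b)) == (fn(a, b),), kind

    def test_inverted_inputs_realize_inhibiting_edges(self):
        c = Circuit("t", ("a", "b"), ("g",),
                    (Gate("g", "AND", ("a", "b"), frozenset({1})),))
        # g = a AND NOT b
        assert [evaluate(c, x)[0] for x in
                [(0, 0), (0, 1), (1, 0), (1, 1)]] == [0, 0, 1, 0]


class TestDrugAndFaultSemantics:
    """Two-gate fixtures pinning the pre/post-drug fault convention."""

    @staticmethod
    def drugged_wire():
        return Circuit(
            "dw", ("a",), ("out",),
            (Gate("mid", "BUF", ("a",)), Gate("out", "BUF", ("mid",))),
            fault_sites=(FaultSite(1, "mid", 1, "pre_drug"),
                         FaultSite(2, "mid", 1, "post_drug")),
            drug_points=(DrugPoint(0, "inh", "mid"),))

    def test_drug_forces_target_line_to_zero(self):
        c = self.drugged_wire()
        for a in (0, 1):
            assert evaluate(c, (a,), (1,)) == (0,)

    def test_pre_drug_fault_is_nullified_by_the_drug(self):
        c = self.drugged_wire()
        assert evaluate(c, (0,), (0,), [1]) == (1,)
        assert evaluate(c, (0,), (1,), [1]) == (0,)

    def test_post_drug_fault_is_immune_to_the_drug(self):
        c = self.drugged_wire()
        assert evaluate(c, (0,), (0,), [2]) == (1,)
        assert evaluate(c, (0,), (1,), [2]) == (1,)


class TestHammingWeight:
    @pytest.mark.parametrize("bits,expected", [
        ((0, 0, 0, 0, 0, 0), 0),
        ((0, 0, 1, 0, 0, 0), 1),
        ((1, 1, 1, 1, 1, 1), 6),
    ])
    def test_examples(self, bits, expected):
        assert hamming_weight(bits) == expected


class TestStreams:
    def test_length_one_stream_reduces_to_evaluate(self, toy):
        X = np.array([[1, 1, 0, 0]])
        assert tuple(evaluate_streams(toy, X)[0]) == evaluate(
            toy, (1, 1, 0, 0))

    def test_constant_streams_replicate_scalar_result(self, reference):
        L = 64
        X = np.tile(np.array(X_STAR, dtype=np.uint8), (L, 1))
        Z = evaluate_streams(reference, X)
        assert Z.shape == (L, 6)
        assert not Z.any()

    def test_and_gate_on_independent_half_streams(self):
        from oncocircuit import non_bernoulli_stream, decode_stream
        c = Circuit("and2", ("a", "b"), ("g",),
                    (Gate("g", "AND", ("a", "b")),))
        L = 20_000
        X = np.column_stack([non_bernoulli_stream(0.5, L, s).bits
                             for s in (11, 12)])
        p = decode_stream(evaluate_streams(c, X)[:, 0])
        assert abs(p - 0.25) <= 3 * (0.25 * 0.75 / L) ** 0.5

    def test_wrong_column_count_is_contract_error(self, toy):
        with pytest.raises(CircuitError, match="shape"):
            evaluate_streams(toy, np.zeros((4, 3), dtype=np.uint8))

    @given(seed=st.integers(0, 50), data=st.data())
    def test_streams_bitwise_identical_to_rowwise_evaluate(self, seed, data):
        c = random_circuit(FixtureSpec(n_inputs=3, n_gates=6, n_outputs=2,
                                       seed=seed))
        rows = data.draw(st.lists(
            st.tuples(*[st.integers(0, 1)] * 3), min_size=1, max_size=8))
        labels = data.draw(st.sets(
            st.sampled_from(range(1, c.n_fault_sites + 1))
            if c.n_fault_sites else st.nothing(),
            max_size=min(2, c.n_fault_sites)))
        d = data.draw(st.tuples(*[st.integers(0, 1)] * 7))
        X = np.array(rows, dtype=np.uint8)
        Z = evaluate_streams(c, X, d, labels or None)
        for i, row in enumerate(rows):
            assert tuple(Z[i]) == evaluate(c, row, d, labels or None)


class TestTopologicalInvariance:
    @given(seed=st.integers(0, 30), perm_seed=st.integers(0, 10))
    def test_gate_list_order_does_not_matter(self, seed, perm_seed):
        c = random_circuit(FixtureSpec(n_inputs=3, n_gates=7, seed=seed))
        rng = np.random.default_rng(perm_seed)
        order = rng.permutation(len(c.gates))
        shuffled = Circuit(c.name, c.inputs, c.outputs,
                           tuple(c.gates[i] for i in order),
                           c.fault_sites, c.drug_points)
        for x in itertools.product((0, 1), repeat=3):
            assert evaluate(c, x) == evaluate(shuffled, x)


def test_round_trip_serialization(reference, toy):
    for c in (reference, toy):
        again = loads_circuit(json.dumps(dump_circuit(c)))
        assert again == c
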