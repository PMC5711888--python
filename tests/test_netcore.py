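"""Parsing, serialization, evaluation and the synchronous update map."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angionet.netcore import (
    BooleanNetwork,
    NetworkError,
    ParseError,
    evaluate,
    parse_expression,
    parse_network,
    synchronous_step,
    to_string,
    write_network,
)
from angionet.randomnet import RandomNetworkSpec, generate_random_network


class TestParsing:
    def test_two_node_document(self):
        net = parse_network("targets, factors\nAKT, PIP3\nPIP3, AKT")
        assert net.nodes == ("AKT", "PIP3")
        assert to_string(net.rules["AKT"]) == "PIP3"

    def test_operator_precedence_not_and_or(self):
        # !B & (C | A) must bind NOT tightest, then AND, then OR
        e = parse_expression("!B & (C | A)")
        assert evaluate(e, {"A": 1, "B": 0, "C": 0}) == 1
        assert evaluate(e, {"A": 1, "B": 1, "C": 1}) == 0
        e2 = parse_expression("A | B & C")
        assert evaluate(e2, {"A": 1, "B": 0, "C": 0}) == 1
        assert evaluate(e2, {"A": 0, "B": 1, "C": 0}) == 0

    def test_comments_and_blank_lines_ignored(self):
        net = parse_network("# model\ntargets, factors\n\nA, !A # oscillator\n")
        assert net.nodes == ("A",)

    @pytest.mark.parametrize(
        "doc,fragment",
        [
            ("A, B", "targets, factors"),              # missing header
            ("targets, factors\nA, B |", "line 2"),     # dangling operator
            ("targets, factors\nA, C", "undeclared"),   # unknown reference
            ("targets, factors\nA, A\nA, !A", "duplicate"),
        ],
    )
    def test_errors_carry_context(self, doc, fragment):
        with pytest.raises(NetworkError) as err:
            parse_network(doc)
        assert fragment.lower() in str(err.value).lower()

    def test_strict_input_must_self_loop(self):
        doc = "targets, factors\nA, B\nB, B"
        with pytest.raises(NetworkError, match="self-loop"):
            parse_network(doc, ["A"])
        lenient = parse_network(doc, ["A"], strict=False)
        assert lenient.inputs == ("A",)


class TestSerialization:
    def test_single_node_roundtrip(self):
        assert write_network(parse_network("targets, factors\nA, !A")) == (
            "targets, factors\nA, !A\n"
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 10))
    def test_write_parse_write_is_fixpoint(self, seed, n):
        net = generate_random_network(RandomNetworkSpec(n=n, seed=seed))
        once = write_network(net)
        again = write_network(parse_network(once))
        assert once == again

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 10))
    def test_roundtrip_preserves_structure(self, seed, n):
        net = generate_random_network(RandomNetworkSpec(n=n, seed=seed))
        back = parse_network(write_network(net))
        assert back.nodes == net.nodes
        assert back.rules == net.rules

    def test_bundled_model_reparses(self, net):
        again = parse_network(write_network(net), net.inputs)
        assert again.n == 64
        assert len(again.inputs) == 16
        assert again.rules == net.rules


class TestEvaluation:
    def test_energy_stress_rule(self, net):
        # AMPK is ON exactly when energy or oxygen is short and AKT is off
        rule = net.rules["AMPK"]
        assert evaluate(rule, {"AMPATP": 0, "Oxygen": 0, "AKT": 0}) == 1
        assert evaluate(rule, {"AMPATP": 1, "Oxygen": 1, "AKT": 0}) == 1
        assert evaluate(rule, {"AMPATP": 0, "Oxygen": 1, "AKT": 0}) == 0
        assert evaluate(rule, {"AMPATP": 1, "Oxygen": 0, "AKT": 1}) == 0

    def test_calcium_rule(self, net):
        rule = net.rules["Calcium"]
        assert evaluate(rule, {"PLCg": 0, "ShearStress": 0, "NO": 0}) == 1
        assert evaluate(rule, {"PLCg": 0, "ShearStress": 0, "NO": 1}) == 0

    def test_constant_expression(self):
        e = parse_expression("1")
        assert evaluate(e, {}) == 1

    def test_unassigned_reference_raises(self):
        with pytest.raises(NetworkError, match="unassigned"):
            evaluate(parse_expression("A"), {})


class TestSynchronousStep:
    def test_simultaneous_not_sequential(self, toy_swap):
        # A <- B, B <- A from (1,0) must swap to (0,1); an in-place update
        # would collapse to (0,0) or (1,1)
        s = toy_swap.pack_state({"A": 1, "B": 0})
        out = synchronous_step(toy_swap, s)
        assert toy_swap.unpack_state(out) == {"A": 0, "B": 1}

    def test_hand_evaluated_two_node_step(self, toy_rotor):
        s = toy_rotor.pack_state({"A": 1, "B": 0})
        assert toy_rotor.unpack_state(synchronous_step(toy_rotor, s)) == {"A": 1, "B": 1}

    def test_fixed_point_maps_to_itself(self):
        net = parse_network("targets, factors\nA, A\nB, A & B")
        s = net.pack_state({"A": 1, "B": 1})
        assert synchronous_step(net, s) == s

    def test_inputs_conserved_along_trajectories(self, net):
        import numpy as np

        rng = np.random.default_rng(7)
        input_mask = 0
        for name in net.inputs:
            input_mask |= 1 << net.index(name)
        for _ in range(20):
            s = int(rng.integers(0, 2**63)) * 2 + int(rng.integers(0, 2))
            cur = s
            for _ in range(8):
                cur = synchronous_step(net, cur)
                assert (cur & input_mask) == (s & input_mask)

    def test_determinism(self, net):
        s = net.pack_state({n: (i % 2) for i, n in enumerate(net.nodes)})
        assert synchronous_step(net, s) == synchronous_step(net, s)

    def test_vectorized_step_matches_scalar(self, net):
        import numpy as np

        rng = np.random.default_rng(11)
        states = rng.integers(0, 2**63, size=50, dtype=np.uint64)
        step = net.step_function()
        batch = step(states)
        for s, expected in zip(states.tolist(), batch.tolist()):
            assert step(int(s)) == int(expected)


class TestStateHelpers:
    def test_pack_unpack_roundtrip(self, net):
        assignment = {n: (i * 7 % 3 == 0) * 1 for i, n in enumerate(net.nodes)}
        assert net.unpack_state(net.pack_state(assignment)) == assignment

    def test_bits_roundtrip(self, net):
        s = net.pack_state({n: (i % 2) for i, n in enumerate(net.nodes)})
        assert net.state_from_bits(net.state_bits(s)) == s
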