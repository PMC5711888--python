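"""Network simplification: input removal, output removal, contraction."""

import pytest

from angionet.attractors import enumerate_attractors_bruteforce
from angionet.netcore import NetworkError, parse_network, to_string, write_network
from angionet.randomnet import RandomNetworkSpec, generate_random_network
from angionet.reduction import (
    contract_intermediaries,
    remove_constant_inputs,
    remove_outputs,
    replay,
)


def _project(states, indices):
    return frozenset(
        frozenset(
            sum(((s >> i) & 1) << j for j, i in enumerate(indices)) for s in fs
        )
        for fs in states
    )


class TestRemoveConstantInputs:
    def test_constant_folds_into_rules(self):
        net = parse_network("targets, factors\nA, A\nB, A & C\nC, C", ["A", "C"])
        reduced, log = remove_constant_inputs(net, {"A": 1})
        assert reduced.nodes == ("B", "C")
        assert to_string(reduced.rules["B"]) == "C"
        assert len(log.ops) == 1

    def test_non_input_rejected(self):
        net = parse_network("targets, factors\nA, A\nB, A", ["A"])
        with pytest.raises(NetworkError, match="not a declared input"):
            remove_constant_inputs(net, {"B": 1})

    def test_attractors_restricted_and_projected(self):
        # reduced attractors equal original attractors restricted to the
        # states where the input holds its fixed value, projected down
        for seed in range(12):
            base = generate_random_network(RandomNetworkSpec(n=7, seed=seed))
            doc = write_network(base).replace("n0,", "IN,").splitlines()
            doc[1] = "IN, IN"
            text = "\n".join(doc).replace("n0", "IN")
            net = parse_network(text, ["IN"])
            for value in (0, 1):
                reduced, _ = remove_constant_inputs(net, {"IN": value})
                lhs = {
                    frozenset(s >> 1 for s in a.states)
                    for a in enumerate_attractors_bruteforce(net).attractors
                    if all((s & 1) == value for s in a.states)
                }
                rhs = {
                    frozenset(a.states)
                    for a in enumerate_attractors_bruteforce(reduced).attractors
                }
                assert lhs == rhs, f"seed {seed} value {value}"


class TestRemoveOutputs:
    def test_unreferenced_node_dropped(self):
        net = parse_network("targets, factors\nA, A\nB, A")
        reduced, log = remove_outputs(net)
        assert reduced.nodes == ("A",)
        assert [op.node for op in log.ops] == ["B"]

    def test_iterated_removal_of_chain(self):
        net = parse_network("targets, factors\nA, A\nB, A\nC, B")
        reduced, log = remove_outputs(net)
        assert reduced.nodes == ("A",)
        assert {op.node for op in log.ops} == {"B", "C"}

    def test_attractor_projection_equality(self):
        for seed in range(20):
            net = generate_random_network(RandomNetworkSpec(n=8, seed=seed))
            reduced, _ = remove_outputs(net)
            keep = [net.index(n) for n in reduced.nodes]
            lhs = _project(
                {a.states for a in enumerate_attractors_bruteforce(net).attractors},
                keep,
            )
            rhs = frozenset(
                frozenset(a.states)
                for a in enumerate_attractors_bruteforce(reduced).attractors
            )
            assert lhs == rhs, f"seed {seed}"


class TestContraction:
    def test_positive_relay_inlined(self):
        net = parse_network("targets, factors\nA, A\nB, A\nC, B")
        reduced, log = contract_intermediaries(net)
        assert "B" not in reduced.nodes
        assert to_string(reduced.rules["C"]) in ("A",)

    def test_negative_relay_keeps_polarity(self):
        net = parse_network("targets, factors\nA, A\nB, !A\nC, B")
        reduced, _ = contract_intermediaries(net)
        assert to_string(reduced.rules["C"]) == "!A"

    def test_protected_node_kept(self):
        net = parse_network("targets, factors\nA, A\nB, A\nC, B")
        reduced, _ = contract_intermediaries(net, protected={"B"})
        assert "B" in reduced.nodes

    def test_no_self_loop_created(self):
        # contracting B in A <- B, B <- A would create a self-loop: forbidden
        net = parse_network("targets, factors\nA, B\nB, A")
        reduced, log = contract_intermediaries(net)
        assert reduced.nodes == ("A", "B") and not log.ops

    def test_fixed_points_preserved_off_feedback(self):
        # relays not on any cycle: fixed points survive projection
        preserved = 0
        for seed in range(40):
            net = generate_random_network(RandomNetworkSpec(n=8, seed=1000 + seed))
            reduced, log = contract_intermediaries(net)
            if not log.ops:
                continue
            contracted = {op.node for op in log.ops}
            # skip fixtures where a contracted node sat on a feedback circuit
            if _on_cycle(net, contracted):
                continue
            preserved += 1
            keep = [net.index(n) for n in reduced.nodes]
            lhs = {
                sum(((s >> i) & 1) << j for j, i in enumerate(keep))
                for a in enumerate_attractors_bruteforce(net).attractors
                if a.is_fixed_point
                for s in a.states
            }
            rhs = {
                a.states[0]
                for a in enumerate_attractors_bruteforce(reduced).attractors
                if a.is_fixed_point
            }
            assert lhs == rhs, f"seed {1000 + seed}"
        assert preserved >= 5  # the property was actually exercised


def _on_cycle(net, nodes):
    import networkx as nx

    g = nx.DiGraph()
    for v in net.nodes:
        for u in net.rules[v].variables():
            g.add_edge(u, v)
    cyc_nodes = set().union(*nx.simple_cycles(g), set())
    return bool(nodes & cyc_nodes)


class TestReplay:
    def test_replay_reproduces_reduction(self):
        for seed in range(10):
            net = generate_random_network(RandomNetworkSpec(n=8, seed=seed))
            reduced, log1 = remove_outputs(net)
            reduced2, log2 = contract_intermediaries(reduced)
            log1.extend(log2)
            replayed = replay(net, log1)
            assert replayed.nodes == reduced2.nodes
            assert replayed.rules == reduced2.rules
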