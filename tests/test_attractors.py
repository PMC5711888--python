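"""Trajectory iteration, brute-force oracle, clamping, exact enumeration."""

import pytest

from angionet.attractors import (
    MicroEnvironment,
    basin_sizes,
    clamp_inputs,
    core_orbits,
    enumerate_attractors_bruteforce,
    enumerate_attractors_env,
    iterate_to_attractor,
    propagate_constants,
)
from angionet.netcore import Const, NetworkError, parse_network
from angionet.randomnet import RandomNetworkSpec, generate_random_network


class TestIterateToAttractor:
    def test_fixed_point_zero_transient(self):
        net = parse_network("targets, factors\nA, A")
        att, transient = iterate_to_attractor(net, 1)
        assert att.is_fixed_point and att.states == (1,) and transient == 0

    def test_negation_oscillator(self, toy_negation):
        att, transient = iterate_to_attractor(toy_negation, 0)
        assert att.length == 2 and transient == 0

    def test_four_cycle_by_hand(self, toy_rotor):
        # A <- !B, B <- A cycles (0,0)->(1,0)->(1,1)->(0,1)->
        att, transient = iterate_to_attractor(toy_rotor, 0)
        assert transient == 0
        assert att.length == 4
        assert set(att.states) == {0b00, 0b01, 0b10, 0b11}

    def test_transient_counted(self):
        # C <- C makes half the states transient into the C-fixed subspace
        net = parse_network("targets, factors\nA, B\nB, B")
        att, transient = iterate_to_attractor(net, net.pack_state({"A": 1, "B": 0}))
        assert att.is_fixed_point
        assert transient == 1


class TestBruteForce:
    def test_identity_node_two_fixed_points(self):
        net = parse_network("targets, factors\nA, A")
        aset = enumerate_attractors_bruteforce(net)
        assert aset.lengths == [1, 1]

    def test_rotor_single_four_cycle(self, toy_rotor):
        aset = enumerate_attractors_bruteforce(toy_rotor)
        assert len(aset) == 1 and aset.lengths == [4]

    def test_matches_per_state_iteration(self):
        net = parse_network("targets, factors\nA, A\nB, A & C\nC, B")
        aset = enumerate_attractors_bruteforce(net)
        found = {iterate_to_attractor(net, s)[0] for s in range(8)}
        assert aset.attractors == frozenset(found)

    def test_cap_enforced(self):
        net = generate_random_network(RandomNetworkSpec(n=8, seed=1))
        with pytest.raises(NetworkError, match="capped"):
            enumerate_attractors_bruteforce(net, cap=6)

    def test_basins_partition_state_space(self):
        for seed in range(5):
            net = generate_random_network(RandomNetworkSpec(n=8, seed=seed))
            sizes = basin_sizes(net)
            assert sum(sizes.values()) == 2**8


class TestClamping:
    def test_shear_stress_forces_klf2(self, net, meta):
        env = MicroEnvironment.from_assignment(
            meta["inputs"], {n: int(n == "ShearStress") for n in meta["inputs"]}
        )
        clamped = clamp_inputs(net, env)
        assert clamped.rules["KLF2"] == Const(1)

    def test_no_wnt_silences_betacatenin(self, net, meta):
        env = MicroEnvironment.from_code(meta["inputs"], 0)
        clamped = clamp_inputs(net, env)
        assert clamped.rules["betacatenin"] == Const(0)

    def test_at_most_48_free_nodes(self, net, meta):
        for code in (0, 65535, 12345):
            env = MicroEnvironment.from_code(meta["inputs"], code)
            fixed, free = propagate_constants(net, env.assignment)
            assert len(free) <= 48
            assert len(fixed) + len(free) == 64

    def test_propagation_is_sound_on_attractors(self, net, meta):
        # every enumerated attractor state agrees with the propagated constants
        env = MicroEnvironment.from_code(meta["inputs"], 40000)
        fixed, _ = propagate_constants(net, env.assignment)
        for att in enumerate_attractors_env(net, env):
            for name, value in fixed.items():
                assert att.values(name) == (value,) * att.length

    def test_unknown_node_rejected(self, net):
        with pytest.raises(NetworkError):
            propagate_constants(net, {"NotANode": 1})


class TestEnvironmentEnumeration:
    def test_environment_code_roundtrip(self, meta):
        names = meta["inputs"]
        for code in (0, 1, 37, 65535):
            env = MicroEnvironment.from_code(names, code)
            assert env.code == code
            assert MicroEnvironment.from_assignment(names, env.assignment) == env

    def test_first_input_is_most_significant(self, meta):
        env = MicroEnvironment.from_code(meta["inputs"], 1 << 15)
        assert env.assignment["VEGFC_Dp"] == 1
        assert sum(env.assignment.values()) == 1

    def test_input_projection_matches_environment(self, net, meta):
        env = MicroEnvironment.from_code(meta["inputs"], 23456)
        for att in enumerate_attractors_env(net, env):
            for name, value in env.assignment.items():
                assert att.values(name) == (value,) * att.length

    def test_closure_and_minimality(self, net, meta):
        from angionet.netcore import synchronous_step

        env = MicroEnvironment.from_code(meta["inputs"], 516)
        for att in enumerate_attractors_env(net, env):
            states = att.states
            for i, s in enumerate(states):
                assert synchronous_step(net, s) == states[(i + 1) % att.length]
            assert len(set(states)) == att.length

    def test_canonical_form_independent_of_discovery(self, toy_rotor):
        from angionet.attractors import Attractor

        a = Attractor(("A", "B"), [0, 2, 3, 1])
        b = Attractor(("A", "B"), [3, 1, 0, 2])
        assert a == b and a.id() == b.id()

    @pytest.mark.parametrize("backend", ["scc", "bdd"])
    def test_backends_match_bruteforce_oracle(self, backend):
        # random closed networks: treat every node as free core
        for seed in range(25):
            net = generate_random_network(RandomNetworkSpec(n=10, seed=100 + seed))
            oracle = enumerate_attractors_bruteforce(net)
            orbits = core_orbits(list(net.nodes), dict(net.rules), backend)
            got = {
                frozenset(net.pack_state(a) for a in orbit) for orbit in orbits
            }
            expected = {frozenset(a.states) for a in oracle.attractors}
            assert got == expected, f"seed {100 + seed} backend {backend}"

    def test_pointer_backend_matches_oracle(self):
        for seed in range(8):
            net = generate_random_network(RandomNetworkSpec(n=14, seed=seed))
            oracle = enumerate_attractors_bruteforce(net)
            orbits = core_orbits(list(net.nodes), dict(net.rules), "pointer")
            got = {frozenset(net.pack_state(a) for a in orbit) for orbit in orbits}
            assert got == {frozenset(a.states) for a in oracle.attractors}
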