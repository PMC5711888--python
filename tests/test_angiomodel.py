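"""The bundled model: signatures, classification, worked environments,
behavior transitions."""

import itertools

import pytest

from angionet.angiomodel import (
    behavior_transition,
    classify_attractor,
    classify_proliferation,
    classify_state,
    group_environments,
    load_model,
)
from angionet.attractors import Attractor, MicroEnvironment, enumerate_attractors_env
from angionet.netcore import NetworkError


def env_with(meta, active):
    return MicroEnvironment.from_assignment(
        meta["inputs"], {n: int(n in active) for n in meta["inputs"]}
    )


BASELINE = {"ANG1", "Oxygen", "ShearStress"}


class TestModelFile:
    def test_dimensions(self, net):
        assert net.n == 64
        assert len(net.inputs) == 16

    def test_every_input_is_self_loop(self, net):
        from angionet.netcore import Var

        for name in net.inputs:
            assert net.rules[name] == Var(name)


class TestSignatures:
    def test_state_level_examples(self):
        tip = {"NRP1": 1, "DLL4a": 1, "AKT": 0, "JAGa": 0}
        assert classify_state(tip) == "Tip"
        stalk = {"NRP1": 0, "DLL4a": 1, "AKT": 1, "JAGa": 1}
        assert classify_state(stalk) == "Stalk"
        other = {"NRP1": 0, "DLL4a": 0, "AKT": 0, "JAGa": 0}
        assert classify_state(other) == "Other"

    def test_mutual_exclusivity_exhaustive(self):
        # no assignment of the four markers satisfies two signatures
        for bits in itertools.product((0, 1), repeat=4):
            st = dict(zip(("NRP1", "DLL4a", "AKT", "JAGa"), bits))
            matches = [
                label
                for label, sig in (
                    ("Tip", {"NRP1": 1, "DLL4a": 1, "AKT": 0}),
                    ("Stalk", {"JAGa": 1, "NRP1": 0}),
                    ("Phalanx", {"AKT": 1, "JAGa": 0, "NRP1": 0}),
                )
                if all(st[m] == v for m, v in sig.items())
            ]
            assert len(matches) <= 1

    def test_missing_marker_raises(self):
        with pytest.raises(NetworkError):
            classify_state({"NRP1": 1})


class TestAttractorClassification:
    def test_fixed_point_keeps_state_label(self, net, meta):
        env = env_with(meta, BASELINE)
        (att,) = enumerate_attractors_env(net, env)
        assert att.is_fixed_point
        assert classify_attractor(net, att) == "Phalanx"

    def test_mixed_cycle_is_atypical(self, net):
        tip = {n: 0 for n in net.nodes}
        tip.update({"NRP1": 1, "DLL4a": 1})
        stalk = {n: 0 for n in net.nodes}
        stalk.update({"JAGa": 1})
        fake = Attractor(net.nodes, [net.pack_state(tip), net.pack_state(stalk)])
        assert classify_attractor(net, fake) == "Atypical"

    def test_all_other_cycle_is_atypical(self, net):
        blank = {n: 0 for n in net.nodes}
        second = dict(blank, Calcium=1)
        fake = Attractor(net.nodes, [net.pack_state(blank), net.pack_state(second)])
        assert classify_attractor(net, fake) == "Atypical"

    def test_proliferation_requires_both_markers_throughout(self, net):
        grow = {n: 0 for n in net.nodes}
        grow.update({"betacatenin": 1, "LEF1": 1})
        assert classify_proliferation(net, Attractor(net.nodes, [net.pack_state(grow)]))
        half = dict(grow, LEF1=0)
        two = Attractor(net.nodes, [net.pack_state(grow), net.pack_state(half)])
        assert not classify_proliferation(net, two)


class TestWorkedEnvironments:
    """The four reference micro-environments drive the expected behaviors."""

    @pytest.mark.parametrize(
        "extra,expected",
        [
            (set(), "Phalanx"),
            ({"VEGFC_Dp"}, "Tip"),
            ({"VEGFAxxxP"}, "Tip"),
            ({"DLL4p", "WNT5a", "TGFB1"}, "Stalk"),
        ],
    )
    def test_all_attractors_carry_expected_label(self, net, meta, extra, expected):
        env = env_with(meta, BASELINE | extra)
        aset = enumerate_attractors_env(net, env)
        assert len(aset) >= 1
        for att in aset:
            assert classify_attractor(net, att) == expected

    def test_tip_environment_marker_values(self, net, meta):
        env = env_with(meta, BASELINE | {"VEGFAxxxP"})
        for att in enumerate_attractors_env(net, env):
            assert set(att.values("NRP1")) == {1}
            assert set(att.values("DLL4a")) == {1}
            assert set(att.values("AKT")) == {0}

    def test_phalanx_environment_marker_values(self, net, meta):
        env = env_with(meta, BASELINE)
        for att in enumerate_attractors_env(net, env):
            assert set(att.values("AKT")) == {1}
            assert set(att.values("JAGa")) == {0}
            assert set(att.values("NRP1")) == {0}


class TestBehaviorTransition:
    def test_same_environment_is_noop(self, net, meta):
        env = env_with(meta, BASELINE)
        (att,) = enumerate_attractors_env(net, env)
        result = behavior_transition(net, att.states[0], env)
        assert result.transient_length == 0
        assert result.attractor == att

    def test_phalanx_to_tip(self, net, meta):
        (phalanx,) = enumerate_attractors_env(net, env_with(meta, BASELINE))
        to_env = env_with(meta, BASELINE | {"VEGFC_Dp"})
        result = behavior_transition(net, phalanx.states[0], to_env)
        assert result.label == "Tip"

    def test_tip_to_stalk(self, net, meta):
        tip_env = env_with(meta, BASELINE | {"VEGFAxxxP"})
        (tip,) = enumerate_attractors_env(net, tip_env)
        to_env = env_with(meta, BASELINE | {"DLL4p", "WNT5a", "TGFB1"})
        result = behavior_transition(net, tip.states[0], to_env)
        assert result.label == "Stalk"

    def test_internal_state_carried_over(self, net, meta):
        (phalanx,) = enumerate_attractors_env(net, env_with(meta, BASELINE))
        to_env = env_with(meta, BASELINE | {"VEGFC_Dp"})
        result = behavior_transition(net, phalanx.states[0], to_env)
        first = result.trajectory[0]
        for name in net.nodes:
            bit = (first >> net.index(name)) & 1
            if name in net.inputs:
                assert bit == to_env.assignment[name]
            else:
                assert bit == (phalanx.states[0] >> net.index(name)) & 1

    def test_non_attractor_start_rejected(self, net, meta):
        env = env_with(meta, BASELINE)
        (att,) = enumerate_attractors_env(net, env)
        # flip one internal (non-input) bit off the attractor
        bad = att.states[0] ^ (1 << net.index("AKT"))
        with pytest.raises(NetworkError, match="not part of an attractor"):
            behavior_transition(net, bad, env)


class TestGrouping:
    def test_groups_cover_label_disjointly(self, wild_type_sweep):
        groups = group_environments(wild_type_sweep, "Phalanx")
        total = sum(g["n_environments"] for g in groups)
        assert total == wild_type_sweep.behavior_counts()["Phalanx"]
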