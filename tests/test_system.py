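"""Cause-effect structures, system cuts, constellation distance, Phi."""

import numpy as np
import pytest

import boxphi as bp
from boxphi.network import (CandidateSystem, MicroNetwork, TruthTable,
                            build_transition_model)
from boxphi.system import (MicroAnalysisSystem, SystemCut,
                           UndefinedCauseEffectStructure, apply_system_cut,
                           ces_distance, compute_big_phi, compute_ces)

from _oracles import NaivePhi


def micro_system(net, state, background=None):
    background = dict(background or {})
    nodes = tuple(l for l in net.node_labels if l not in background)
    return CandidateSystem(net, nodes, background,
                           tuple(state[net.index(l)] if isinstance(state, tuple)
                                 else state[l] for l in nodes))


class TestComputeCes:
    def test_xor_delay_micro_has_three_first_order_concepts(
            self, xor_micro_system):
        ces = compute_ces(xor_micro_system)
        assert sorted(c.mechanism for c in ces.concepts) == [(0,), (3,), (6,)]
        assert all(c.phi == pytest.approx(0.5, abs=1e-9)
                   for c in ces.concepts)

    def test_macro_xor_has_three_second_order_concepts(self, xor_macro):
        ces = compute_ces(xor_macro)
        assert sorted(c.mechanism for c in ces.concepts) == \
            [(0, 1), (0, 2), (1, 2)]
        assert all(c.phi == pytest.approx(0.5, abs=1e-9)
                   for c in ces.concepts)

    def test_cell_cycle_t2_is_undefined(self, cell_cycle):
        net = cell_cycle.network
        t2 = dict(zip(net.node_labels, cell_cycle.sequence.states[1]))
        sys8 = micro_system(net, t2, {"SK": 0})
        with pytest.raises(UndefinedCauseEffectStructure):
            compute_ces(sys8)


class TestSystemCuts:
    def test_cut_severing_nothing_leaves_model_unchanged(self):
        # a -> b -> c chain: cutting {c} -> {a,b} severs no connection
        labels = ("a", "b", "c")
        net = MicroNetwork(labels,
                           {l: TruthTable((0.0, 1.0)) for l in labels},
                           {"a": ("c",), "b": ("a",), "c": ("b",)})
        sys3 = micro_system(net, (0, 0, 0))
        asys = MicroAnalysisSystem(sys3)
        cut = SystemCut(("b",), ("c",))   # b -> c is a real connection
        uncut = SystemCut(("b",), ("a",))  # b -> a does not exist
        m = apply_system_cut(asys, uncut)
        for a, b in zip(m.nodes, asys.model.nodes):
            assert a.inputs == b.inputs and np.allclose(a.table, b.table)
        m2 = apply_system_cut(asys, cut)
        assert m2.nodes[2].pruned().inputs == ()   # c now reads pure noise

    def test_two_node_loop_cut_makes_receiver_uniform(self):
        net = MicroNetwork(("a", "b"),
                           {"a": TruthTable((0.0, 1.0)),
                            "b": TruthTable((1.0, 0.0))},   # b = NOT a
                           {"a": ("b",), "b": ("a",)})
        asys = MicroAnalysisSystem(micro_system(net, (0, 0)))
        m = apply_system_cut(asys, SystemCut(("a",), ("b",)))
        bmod = m.nodes[1].pruned()
        assert bmod.inputs == () and bmod.table == pytest.approx(0.5)
        amod = m.nodes[0].pruned()
        assert amod.inputs == (1,)       # a still reads b

    def test_cut_copy_to_xor_noises_one_input(self, xor_micro_system):
        asys = MicroAnalysisSystem(xor_micro_system)
        rest = tuple(l for l in asys.labels if l != "C12")
        m = apply_system_cut(asys, SystemCut(("C12",), rest))
        x1 = m.nodes[0].pruned()
        # X1 = XOR(noise, C13): both values equally likely whatever C13 is
        assert x1.inputs == ()
        assert np.allclose(x1.table, 0.5)

    def test_empty_part_rejected(self):
        with pytest.raises(ValueError):
            SystemCut((), ("a",))


class TestCesDistance:
    def test_identical_structures_have_zero_distance(self, xor_micro_system):
        ces = compute_ces(xor_micro_system)
        assert ces_distance(ces, ces) == pytest.approx(0.0, abs=1e-12)

    def test_single_concept_transported_to_null(self, xor_micro_system):
        """Distance between a one-concept structure and the empty structure
        equals phi x (ground distance to the null concept), checked against
        the dense-LP oracle."""
        ces = compute_ces(xor_micro_system)
        one = bp.CauseEffectStructure(
            ces.concepts[:1], ces.labels, ces.state,
            unconstrained_effect=ces.unconstrained_effect)
        empty = bp.CauseEffectStructure(
            [], ces.labels, ces.state,
            unconstrained_effect=ces.unconstrained_effect)
        got = ces_distance(one, empty)
        model = bp.build_transition_model(xor_micro_system.network)
        naive = NaivePhi(model.state_by_state(), (0,) * 9)
        nces = [{
            "mech": ces.concepts[0].mechanism,
            "phi": ces.concepts[0].phi,
            "cause": (ces.concepts[0].cause.purview,
                      ces.concepts[0].cause.repertoire),
            "effect": (ces.concepts[0].effect.purview,
                       ces.concepts[0].effect.repertoire),
        }]
        assert got == pytest.approx(naive.ces_distance(nces, []), abs=1e-7)

    def test_phi_delta_bounds_distance(self, xor_micro_system):
        """Two structures differing only in one concept's phi by delta are
        at most delta x the maximal ground distance apart."""
        ces = compute_ces(xor_micro_system)
        import copy
        ces2 = copy.deepcopy(ces)
        delta = 0.1
        ces2.concepts[0].cause.phi -= delta
        ces2.concepts[0].effect.phi -= delta
        d = ces_distance(ces, ces2)
        n = len(ces.labels)
        max_ground = 2 * n     # cause and effect each at most n apart
        assert 0 <= d <= delta * max_ground + 1e-9

    def test_mismatched_systems_rejected(self, xor_micro_system, xor_macro):
        a = compute_ces(xor_micro_system)
        b = compute_ces(xor_macro)
        with pytest.raises(ValueError):
            ces_distance(a, b)


class TestBigPhi:
    def test_feedback_free_element_makes_system_reducible(self, cell_cycle):
        # SK receives nothing from the rest: any system including it has
        # Phi = 0 (checked in the G1 attractor state, where SK=0 is causable)
        net = cell_cycle.network
        t9 = dict(zip(net.node_labels, cell_cycle.sequence.states[8]))
        res = compute_big_phi(micro_system(net, t9))
        assert res.phi == 0.0
        assert set(res.mip_cut.to_part) == {"SK"}

    def test_isolated_single_element_phi_zero(self):
        net = MicroNetwork(("a", "b"),
                           {"a": TruthTable((0.0, 1.0)),
                            "b": TruthTable((0.0, 1.0))},
                           {"a": ("b",), "b": ("b",)})
        # subsystem {a}: no self-connection once b is background
        sysa = CandidateSystem(net, ("a",), {"b": 0}, (0,))
        assert compute_big_phi(sysa).phi == 0.0

    def test_not_strongly_connected_gives_zero(self):
        # feed-forward chain a -> b -> c
        labels = ("a", "b", "c")
        net = MicroNetwork(labels,
                           {l: TruthTable((0.0, 1.0)) if l != "a"
                            else TruthTable((0.5,)) for l in labels},
                           {"a": (), "b": ("a",), "c": ("b",)})
        res = compute_big_phi(micro_system(net, (0, 0, 0)))
        assert res.phi == 0.0

    def test_phi_invariant_under_relabeling(self):
        for seed in (1, 4):
            net = bp.random_network(3, 2, ("XOR", "NOR"), seed=seed)
            state = (0, 0, 1)
            try:
                r1 = compute_big_phi(micro_system(net, state))
            except UndefinedCauseEffectStructure:
                continue
            order = (2, 0, 1)
            pnet = MicroNetwork(tuple(net.node_labels[i] for i in order),
                                dict(net.functions), dict(net.wiring))
            pstate = tuple(state[i] for i in order)
            r2 = compute_big_phi(micro_system(pnet, pstate))
            assert r1.phi == pytest.approx(r2.phi, abs=1e-7)

    def test_symmetry_pruning_matches_full_enumeration(self):
        for seed in (0, 2, 5):
            net = bp.random_network(4, 2, ("XOR", "NOR", "OR"), seed=seed)
            state = (0, 0, 0, 0)
            try:
                full = compute_big_phi(micro_system(net, state))
            except UndefinedCauseEffectStructure:
                continue
            pruned = compute_big_phi(micro_system(net, state), symmetry=True)
            assert pruned.phi == pytest.approx(full.phi, abs=1e-9)
            assert pruned.cuts_evaluated <= full.cuts_evaluated

    def test_matches_naive_oracle_on_three_node_systems(self):
        """compute_big_phi vs an independent unpruned re-implementation on
        seeded 3-node systems (dense transportation LPs throughout)."""
        checked = 0
        for seed in range(6):
            net = bp.random_network(3, 2, ("XOR", "OR", "NOR", "AND"),
                                    seed=seed)
            for state in [(0, 0, 0), (1, 0, 1)]:
                model = build_transition_model(net)
                naive = NaivePhi(model.state_by_state(), state)
                expected = naive.big_phi()
                if expected is None:
                    with pytest.raises(UndefinedCauseEffectStructure):
                        compute_big_phi(micro_system(net, state))
                    continue
                res = compute_big_phi(micro_system(net, state))
                assert res.phi == pytest.approx(expected, abs=1e-6)
                checked += 1
        assert checked >= 4

    def test_xor_loop_phi_positive_and_result_reported(self):
        net = MicroNetwork(("a", "b"),
                           {"a": TruthTable((0.0, 1.0)),
                            "b": TruthTable((0.0, 1.0))},
                           {"a": ("b",), "b": ("a",)})
        res = compute_big_phi(micro_system(net, (0, 0)))
        assert res.phi > 0
        assert res.mip_cut is not None
        assert "Phi" in res.summary()
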