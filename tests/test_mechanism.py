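"""Repertoires, earth-mover distance, and mechanism-level phi."""

import itertools

import numpy as np
import pytest

import boxphi as bp
from boxphi.mechanism import Repertoire, RepertoireCalculator
from boxphi.network import build_transition_model

from _oracles import NaivePhi, hamming_emd_oracle

# XOR-delay unit indices (fixture node order)
X1, C12, C13, X2, C21, C23, X3, C31, C32 = range(9)


class TestCauseRepertoires:
    def test_xor_off_constrains_inputs_to_agree(self, xor_micro_calc):
        r = xor_micro_calc.cause_repertoire((X1,), (C12, C13))
        assert np.allclose(r.dist, [0.5, 0.0, 0.0, 0.5])

    def test_copy_off_constrains_its_input_off(self, xor_micro_calc):
        r = xor_micro_calc.cause_repertoire((C12,), (X2,))
        assert np.allclose(r.dist, [1.0, 0.0])

    @pytest.mark.parametrize("purview", [(X1,), (C12, X2), (X1, X2, X3)])
    def test_empty_mechanism_gives_uniform_prior(self, xor_micro_calc, purview):
        r = xor_micro_calc.cause_repertoire((), purview)
        assert np.allclose(r.dist, 1.0 / len(r.dist))

    def test_repertoires_normalise(self, xor_micro_calc):
        rng = np.random.default_rng(0)
        units = list(range(9))
        for _ in range(20):
            mech = tuple(rng.choice(units, rng.integers(1, 4), replace=False))
            pv = tuple(rng.choice(units, rng.integers(1, 4), replace=False))
            r = xor_micro_calc.cause_repertoire(mech, pv)
            if r is not None:
                assert r.dist.sum() == pytest.approx(1.0, abs=1e-9)
            e = xor_micro_calc.effect_repertoire(mech, pv)
            assert e.dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_state_with_no_cause_returns_none(self):
        # a=AND needs past (1,1) to be ON while b=NOR needs past (0,0):
        # the joint state (1,1) is unreachable and has no cause
        from boxphi.network import MicroNetwork, TruthTable
        net = MicroNetwork(
            ("a", "b"),
            {"a": TruthTable((0.0, 0.0, 0.0, 1.0)),   # AND
             "b": TruthTable((1.0, 0.0, 0.0, 0.0))},  # NOR
            {"a": ("a", "b"), "b": ("a", "b")})
        model = build_transition_model(net)
        calc = RepertoireCalculator(model, (1, 1))
        assert calc.cause_repertoire((0, 1), (0, 1)) is None
        assert not calc.state_reachable()


class TestEffectRepertoires:
    def test_copy_pair_off_forces_xor_off(self, xor_micro_calc):
        r = xor_micro_calc.effect_repertoire((C12, C13), (X1,))
        assert np.allclose(r.dist, [1.0, 0.0])

    def test_single_copy_leaves_xor_unconstrained(self, xor_micro_calc):
        r = xor_micro_calc.effect_repertoire((C12,), (X1,))
        assert np.allclose(r.dist, [0.5, 0.5])

    def test_empty_mechanism_marginalises_gate_table(self, xor_micro_calc):
        # XOR is OFF for 2 of its 4 equally likely input states
        r = xor_micro_calc.effect_repertoire((), (X1,))
        assert np.allclose(r.dist, [0.5, 0.5])

    def test_multi_node_purview_factorises(self, xor_micro_calc):
        mech = (X1, C12)
        purview = (C21, C31, X2)
        whole = xor_micro_calc.effect_repertoire(mech, purview).dist
        outer = np.ones(1)
        for j in sorted(purview):  # ascending order is the flat convention
            outer = np.kron(xor_micro_calc.effect_repertoire(mech, (j,)).dist,
                            outer)
        assert np.allclose(whole, outer)


class TestRepertoireDistance:
    def test_identity_is_zero(self):
        a = Repertoire("cause", (0, 1), [0.25] * 4)
        assert bp.repertoire_distance(a, a) == 0.0

    def test_single_unit_transport(self):
        a = Repertoire("cause", (0,), [1.0, 0.0])
        b = Repertoire("cause", (0,), [0.5, 0.5])
        assert bp.repertoire_distance(a, b) == pytest.approx(0.5)

    def test_two_unit_example(self):
        a = Repertoire("cause", (0, 1), [0.5, 0.0, 0.0, 0.5])
        b = Repertoire("cause", (0, 1), [0.25] * 4)
        assert bp.repertoire_distance(a, b) == pytest.approx(0.5)

    def test_mismatched_purviews_rejected(self):
        a = Repertoire("cause", (0,), [1.0, 0.0])
        b = Repertoire("cause", (1,), [1.0, 0.0])
        with pytest.raises(ValueError):
            bp.repertoire_distance(a, b)

    @pytest.mark.parametrize("n_units", [1, 2, 3])
    def test_agrees_with_transportation_lp_oracle(self, n_units):
        """Min-cost flow on the hypercube vs the dense transportation LP,
        100 seeded random distribution pairs."""
        rng = np.random.default_rng(42 + n_units)
        for _ in range(34):
            p = rng.random(1 << n_units)
            q = rng.random(1 << n_units)
            p /= p.sum()
            q /= q.sum()
            assert bp.hamming_emd(p, q) == pytest.approx(
                hamming_emd_oracle(p, q), abs=1e-7)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        p, q = rng.random(8), rng.random(8)
        p /= p.sum()
        q /= q.sum()
        assert bp.hamming_emd(p, q) == pytest.approx(bp.hamming_emd(q, p),
                                                     abs=1e-9)


class TestConcepts:
    @pytest.mark.parametrize("xor_unit", [X1, X2, X3])
    def test_each_xor_specifies_phi_half(self, xor_micro_calc, xor_unit):
        c = xor_micro_calc.concept((xor_unit,))
        assert c is not None
        assert c.phi == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("copy_unit", [C12, C13, C21, C23, C31, C32])
    def test_single_copies_lack_irreducible_effect(self, xor_micro_calc,
                                                   copy_unit):
        c = xor_micro_calc.concept((copy_unit,))
        assert c is None

    def test_copy_pairs_have_reducible_cause(self, xor_micro_calc):
        # the two COPYs feeding one XOR constrain the future irreducibly
        # but their joint cause splits into the two independent inputs
        phi_e, _ = xor_micro_calc.phi_effect((C12, C13), (X1,))
        assert phi_e > 0.1
        assert xor_micro_calc.concept((C12, C13)) is None

    def test_phi_invariant_under_relabeling(self):
        rng = np.random.default_rng(17)
        for seed in range(4):
            net = bp.random_network(4, 2, ("NOR", "XOR", "OR"), seed=seed)
            model = build_transition_model(net)
            state = tuple(rng.integers(0, 2, 4))
            calc = RepertoireCalculator(model, state)
            perm = tuple(rng.permutation(4))
            # permuted network: relabel node i -> position perm[i]
            labels = net.node_labels
            new_order = sorted(range(4), key=lambda i: perm[i])
            pnet = bp.MicroNetwork(
                tuple(labels[i] for i in new_order),
                dict(net.functions),
                dict(net.wiring))
            pmodel = build_transition_model(pnet)
            pstate = tuple(state[i] for i in new_order)
            pcalc = RepertoireCalculator(pmodel, pstate)
            for r in (1, 2):
                for mech in itertools.combinations(range(4), r):
                    c1 = calc.concept(mech)
                    pmech = tuple(sorted(
                        pnet.node_labels.index(labels[i]) for i in mech))
                    c2 = pcalc.concept(pmech)
                    if c1 is None:
                        assert c2 is None
                    else:
                        assert c2 is not None
                        assert c1.phi == pytest.approx(c2.phi, abs=1e-9)

    def test_copy_chain_cause_phi_is_half(self):
        # ring of COPY elements, consistent all-OFF state: each element's
        # cause over its direct input is irreducible with phi = 1/2
        from boxphi.network import MicroNetwork, TruthTable
        labels = ("c0", "c1", "c2")
        net = MicroNetwork(
            labels, {l: TruthTable((0.0, 1.0)) for l in labels},
            {"c0": ("c2",), "c1": ("c0",), "c2": ("c1",)})
        calc = RepertoireCalculator(build_transition_model(net), (0, 0, 0))
        for i, inp in [(0, 2), (1, 0), (2, 1)]:
            phi, _ = calc.phi_cause((i,), (inp,))
            assert phi == pytest.approx(0.5, abs=1e-9)

    def test_small_phi_matches_naive_oracle(self):
        """phi for every mechanism/purview of seeded 3-node systems equals
        the unpruned dense-LP reference."""
        for seed in range(3):
            net = bp.random_network(3, 2, ("XOR", "OR", "NOR"), seed=seed)
            model = build_transition_model(net)
            state = (0, 1, 0)
            calc = RepertoireCalculator(model, state)
            naive = NaivePhi(model.state_by_state(), state)
            for r in range(1, 4):
                for mech in itertools.combinations(range(3), r):
                    for k in range(1, 4):
                        for pv in itertools.combinations(range(3), k):
                            got_c, _ = calc.phi_cause(mech, pv)
                            got_e, _ = calc.phi_effect(mech, pv)
                            assert got_c == pytest.approx(
                                naive.small_phi("cause", mech, pv), abs=1e-7)
                            assert got_e == pytest.approx(
                                naive.small_phi("effect", mech, pv), abs=1e-7)
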