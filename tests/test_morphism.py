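"""Static morphism conditions, composition, and change-of-rates lifting."""

import numpy as np
import pytest

from crnemu import (
    Complex,
    NetworkMorphism,
    RateChange,
    Reaction,
    ValidationError,
    change_of_rates_lift,
    compose,
    fibers,
    identity_morphism,
    is_homomorphism,
    is_net_stoichiomorphism,
    is_reactant_morphism,
    is_stoichiomorphism,
    make_network,
    morphism_from_json,
    stoich_matrices,
    write_crn,
)
from crnemu.netlib import random_crn


def rx(reactants, products, rate=1.0):
    return Reaction(Complex(reactants), Complex(products), rate)


class TestFibers:
    def test_mi_to_am_species_fiber(self, mi_to_am):
        fib = fibers(mi_to_am.species_map, mi_to_am.target.species)
        assert fib["x1"] == {"y_1", "z_1"}
        assert fib["x0"] == {"y_0", "z_2"}

    def test_identity_has_singleton_fibers(self):
        fib = fibers({"a": "a", "b": "b"}, ["a", "b"])
        assert fib == {"a": {"a"}, "b": {"b"}}

    def test_constant_map_has_one_full_fiber(self):
        fib = fibers({"a": "t", "b": "t"}, ["t", "u"])
        assert fib == {"t": {"a", "b"}, "u": set()}


class TestReactantMorphism:
    def test_mi_to_am_holds(self, mi_to_am):
        assert is_reactant_morphism(mi_to_am).holds

    def test_doubled_target_reactants_fail(self):
        src = make_network((), [rx({"s0": 1}, {"s1": 1})])
        tgt = make_network((), [rx({"t0": 2}, {"t1": 1})])
        res = is_reactant_morphism(
            NetworkMorphism(src, tgt, {"s0": "t0", "s1": "t1"}, (0,))
        )
        assert not res.holds
        assert res.witnesses[0][1:] == (1, 2)

    def test_identity_holds(self):
        net = random_crn(3)
        assert is_reactant_morphism(identity_morphism(net)).holds


class TestHomomorphism:
    def test_mi_to_am_holds(self, mi_to_am):
        assert is_homomorphism(mi_to_am).holds

    def test_rate_trade_is_reactant_but_not_homomorphism(self, fig6):
        m = fig6["fig6f"]
        assert is_reactant_morphism(m).holds
        assert not is_homomorphism(m).holds

    def test_homomorphism_implies_reactant_morphism(self, mi_to_am, fig6):
        for m in (mi_to_am, fig6["fig6a"], fig6["fig6b"], fig6["fig6d"]):
            if is_homomorphism(m).holds:
                assert is_reactant_morphism(m).holds

    def test_species_fiber_identity_holds_for_homomorphisms(self, mi_to_am, fig6):
        # mS^T . phi = phi_hat . mR^T
        for m in (mi_to_am, fig6["fig6b"], fig6["fig6d"]):
            assert is_homomorphism(m).holds
            lhs = m.species_matrix.T @ stoich_matrices(m.source).instantaneous
            rhs = stoich_matrices(m.target).instantaneous @ m.reaction_matrix.T
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_species_fiber_identity_does_not_imply_homomorphism(self):
        # doubling both sides preserves fiber-summed phi but is no homomorphism
        src = make_network((), [rx({"s0": 1}, {"s0": 1, "s1": 1})])
        tgt = make_network((), [rx({"t0": 2}, {"t0": 2, "t1": 1})])
        m = NetworkMorphism(src, tgt, {"s0": "t0", "s1": "t1"}, (0,))
        lhs = m.species_matrix.T @ stoich_matrices(src).instantaneous
        rhs = stoich_matrices(tgt).instantaneous @ m.reaction_matrix.T
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        assert not is_homomorphism(m).holds


class TestStoichiomorphism:
    def test_branching_collapse_witness(self, fig6):
        res = is_stoichiomorphism(fig6["fig6b"])
        assert not res.holds
        assert (("s0", 0), -2, -1) in res.witnesses

    def test_product_split_witness(self, fig6):
        res = is_stoichiomorphism(fig6["fig6d"])
        assert not res.holds
        assert (("s1", 0), 1, 2) in res.witnesses

    def test_disjoint_copies_hold(self, fig6):
        m = fig6["fig6a"]
        assert is_homomorphism(m).holds
        assert is_stoichiomorphism(m).holds

    def test_rate_trade_is_stoichiomorphism(self, fig6):
        assert is_stoichiomorphism(fig6["fig6f"]).holds

    def test_net_variant_matches_at_unit_rates(self, mi_to_am):
        assert is_net_stoichiomorphism(mi_to_am).holds == \
            is_stoichiomorphism(mi_to_am).holds is True

    def test_isomorphism_holds(self):
        net = random_crn(9).unit_rates()
        perm = {s: f"P_{s}" for s in net.species}
        from crnemu import homomorphic_projection
        tgt, m = homomorphic_projection(net, perm)
        assert is_net_stoichiomorphism(m).holds
        assert is_stoichiomorphism(m).holds

    def test_checks_do_not_mutate_networks(self, mi_to_am):
        before = (write_crn(mi_to_am.source), write_crn(mi_to_am.target))
        for check in (is_reactant_morphism, is_homomorphism,
                      is_stoichiomorphism, is_net_stoichiomorphism):
            check(mi_to_am)
        assert (write_crn(mi_to_am.source), write_crn(mi_to_am.target)) == before


class TestCompose:
    def test_identity_is_neutral(self, mi_to_am):
        left = compose(identity_morphism(mi_to_am.source), mi_to_am)
        right = compose(mi_to_am, identity_morphism(mi_to_am.target))
        assert left == mi_to_am == right

    def test_characteristic_matrices_multiply(self, mi_to_am, am):
        collapse, cm = __import__("crnemu").homomorphic_projection(
            am, {s: "u" for s in am.species}
        )
        comp = compose(mi_to_am, cm)
        np.testing.assert_array_equal(
            comp.species_matrix, mi_to_am.species_matrix @ cm.species_matrix
        )
        np.testing.assert_array_equal(
            comp.reaction_matrix, mi_to_am.reaction_matrix @ cm.reaction_matrix
        )

    def test_composition_preserves_emulation_conditions(self, mi_to_am, am):
        _, cm = __import__("crnemu").homomorphic_projection(
            am, {s: "u" for s in am.species}
        )
        for m in (mi_to_am, cm):
            assert is_reactant_morphism(m).holds and is_stoichiomorphism(m).holds
        comp = compose(mi_to_am, cm)
        assert is_reactant_morphism(comp).holds
        assert is_stoichiomorphism(comp).holds


class TestChangeOfRates:
    def test_rate_formula(self):
        src = make_network((), [rx({"A": 1}, {"B": 1}, 3.0)])
        tgt = make_network((), [rx({"t0": 1}, {"t1": 2}, 2.0)])
        m = NetworkMorphism(src, tgt, {"A": "t0", "B": "t1"}, (0,))
        new_src, lifted = change_of_rates_lift(m, RateChange({0: 4.0}))
        assert new_src.reactions[0].rate == 6.0  # 3 * 4 / 2
        assert lifted.target.reactions[0].rate == 4.0

    def test_homomorphism_case_copies_rates(self, mi_to_am):
        rc = RateChange({j: 0.25 + j for j in range(mi_to_am.target.n_reactions)})
        new_src, lifted = change_of_rates_lift(mi_to_am, rc)
        for i, r in enumerate(new_src.reactions):
            assert r.rate == rc.assignment[lifted.reaction_map[i]]
        assert is_homomorphism(lifted).holds
        assert is_stoichiomorphism(lifted).holds

    def test_identity_rate_change_is_noop(self, mi_to_am):
        rc = RateChange({j: r.rate for j, r in enumerate(mi_to_am.target.reactions)})
        new_src, lifted = change_of_rates_lift(mi_to_am, rc)
        assert new_src == mi_to_am.source
        assert lifted == mi_to_am

    def test_lift_then_restore_roundtrips(self, mi_to_am):
        rc = RateChange({j: 2.0 + j for j in range(mi_to_am.target.n_reactions)})
        _, lifted = change_of_rates_lift(mi_to_am, rc)
        back = RateChange({j: r.rate for j, r in enumerate(mi_to_am.target.reactions)})
        restored_src, restored = change_of_rates_lift(lifted, back)
        assert restored_src == mi_to_am.source
        assert restored == mi_to_am

    def test_missing_reaction_rejected(self, mi_to_am):
        with pytest.raises(ValidationError, match="misses"):
            change_of_rates_lift(mi_to_am, RateChange({0: 1.0}))


class TestMorphismJson:
    def test_explicit_pairs_roundtrip(self, mi_to_am):
        from crnemu import morphism_to_json
        d = morphism_to_json(mi_to_am)
        m = morphism_from_json(d, mi_to_am.source, mi_to_am.target)
        assert m == mi_to_am

    def test_homomorphic_shorthand_derives_reaction_map(self, mi_to_am):
        m = morphism_from_json(
            {"species": dict(mi_to_am.species_map), "homomorphic": True},
            mi_to_am.source, mi_to_am.target,
        )
        assert m.reaction_map == mi_to_am.reaction_map

    def test_homomorphic_shorthand_errors_on_missing_image(self, mi_to_am, am):
        bad = {s: "x0" for s in mi_to_am.source.species}
        from crnemu import MappingError
        with pytest.raises(MappingError, match="no target reaction"):
            morphism_from_json({"species": bad, "homomorphic": True},
                               mi_to_am.source, am)
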