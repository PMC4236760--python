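"""Mass action, ODE simulation, and dynamic emulation verification."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from crnemu import (
    CRNError,
    Complex,
    Reaction,
    SimulationError,
    check_emulation_derivative,
    check_emulation_trajectory,
    derivatives,
    identity_morphism,
    make_network,
    mass_action,
    pullback_state,
    sample_states,
    simulate,
    steady_state_transfer,
)
from crnemu.netlib import random_crn, random_state


def rx(reactants, products, rate=1.0):
    return Reaction(Complex(reactants), Complex(products), rate)


class TestMassAction:
    def test_product_of_powers(self):
        r = rx({"A": 2, "B": 1}, {"C": 1})
        assert mass_action(r, {"A": 2.0, "B": 3.0}) == 12.0

    def test_empty_reactants_give_unity(self):
        assert mass_action(rx({}, {"A": 1}), {"A": 7.0}) == 1.0

    def test_zero_concentration_annihilates(self):
        assert mass_action(rx({"A": 1, "B": 1}, {}), {"A": 0.0, "B": 5.0}) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(CRNError, match="negative"):
            mass_action(rx({"A": 1}, {}), {"A": -1.0})

    def test_lemma_reactant_morphism_preserves_mass_action(self, mi_to_am, fig6):
        # [r]_{v^ o m} = [m(r)]_{v^} for every reactant morphism
        for m in (mi_to_am, fig6["fig6f"]):
            for v_hat in sample_states(m.target, 100, seed=5):
                v = pullback_state(m.species_map, v_hat)
                for i, r in enumerate(m.source.reactions):
                    image = m.target.reactions[m.reaction_map[i]]
                    assert mass_action(r, v) == pytest.approx(
                        mass_action(image, v_hat), rel=1e-12, abs=1e-300
                    )


class TestDerivatives:
    def test_am_majority_state(self, am):
        dv = derivatives(am, {"x0": 1.0, "x1": 0.0, "x2": 1.0})
        assert dv == {"x0": -1.0, "x1": 2.0, "x2": -1.0}

    def test_mass_conserving_network_sums_to_zero(self, am):
        # every AM reaction preserves total multiplicity
        for v in sample_states(am, 20, seed=1):
            assert sum(derivatives(am, v).values()) == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_reaction_enumeration(self):
        net = random_crn(21, n_species=4, n_reactions=5)
        v = random_state(3, net)
        brute = {s: 0.0 for s in net.species}
        for r in net.reactions:
            ma = mass_action(r, v)
            for s in net.species:
                brute[s] += r.rate * (r.products[s] - r.reactants[s]) * ma
        dv = derivatives(net, v)
        for s in net.species:
            assert dv[s] == pytest.approx(brute[s], rel=1e-12, abs=1e-14)


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        net = make_network((), [rx({"A": 1}, {}, 0.8)])
        traj = simulate(net, {"A": 1.0}, t_end=5.0, grid=51)
        np.testing.assert_allclose(
            traj.values[:, 0], np.exp(-0.8 * traj.times), rtol=1e-6
        )

    def test_zero_state_is_absorbing_without_inflows(self, am):
        traj = simulate(am, {s: 0.0 for s in am.species}, t_end=10.0, grid=11)
        assert np.all(traj.values == 0.0)

    def test_am_majority_wins(self, am):
        traj = simulate(am, {"x0": 2.0, "x1": 0.0, "x2": 1.0}, t_end=200.0, grid=51)
        final = {s: max(v, 0.0) for s, v in traj.state_at(-1).items()}
        assert final["x0"] == pytest.approx(3.0, abs=1e-3)
        assert final["x2"] == pytest.approx(0.0, abs=1e-3)
        assert max(abs(v) for v in derivatives(am, final).values()) < 1e-6

    def test_trajectories_stay_nonnegative(self):
        for seed in range(5):
            net = random_crn(seed, n_species=4, n_reactions=5)
            traj = simulate(net, random_state(seed, net), t_end=5.0, grid=21)
            assert traj.values.min() >= -10 * traj.atol

    def test_bad_horizon_rejected(self, am):
        with pytest.raises(CRNError, match="t_end"):
            simulate(am, {"x0": 1.0}, t_end=0.0)

    def test_csv_layout(self, am):
        traj = simulate(am, {"x0": 1.0, "x1": 0.0, "x2": 0.5}, t_end=1.0, grid=3)
        lines = traj.to_csv().splitlines()
        assert lines[0] == "time,x0,x1,x2"
        assert len(lines) == 4


class TestPullback:
    def test_copies_not_sums(self, mi_to_am):
        v_hat = {"x0": 0.3, "x1": 0.7, "x2": 1.9}
        v = pullback_state(mi_to_am.species_map, v_hat)
        assert v == {"y_0": 0.3, "y_1": 0.7, "y_2": 1.9,
                     "z_0": 1.9, "z_1": 0.7, "z_2": 0.3}

    def test_identity_map(self, am):
        v = {s: 1.0 for s in am.species}
        assert pullback_state({s: s for s in am.species}, v) == v


class TestEmulationChecks:
    def test_derivative_identity_for_emulation(self, mi_to_am):
        states = sample_states(mi_to_am.target, 100, seed=13)
        assert check_emulation_derivative(mi_to_am, states) < 1e-9

    def test_derivative_identity_exact_for_identity_morphism(self, am):
        states = sample_states(am, 10, seed=2)
        assert check_emulation_derivative(identity_morphism(am), states) == 0.0

    def test_counterexamples_fail_at_generic_state(self, fig6):
        for name in ("fig6b", "fig6d"):
            m = fig6[name]
            ones = {s: 1.0 for s in m.target.species}
            assert check_emulation_derivative(m, [ones]) >= 1.0

    def test_trajectory_coincidence(self, mi_to_am):
        v0 = random_state(17, mi_to_am.target)
        rep = check_emulation_trajectory(mi_to_am, v0, t_end=50.0)
        assert rep.verdict
        assert rep.trajectory_deviation < 1e-6

    def test_counterexample_trajectories_diverge(self, fig6):
        m = fig6["fig6b"]
        ones = {s: 1.0 for s in m.target.species}
        rep = check_emulation_trajectory(m, ones, t_end=1.0, grid=51)
        assert not rep.verdict
        assert rep.trajectory_deviation > 1e-2

    def test_identity_morphism_deviation_is_solver_noise(self, am):
        v0 = random_state(23, am)
        rep = check_emulation_trajectory(identity_morphism(am), v0, t_end=10.0)
        assert rep.trajectory_deviation == 0.0

    def test_deviation_stable_under_tolerance_refinement(self, fig6):
        m = fig6["fig6b"]
        ones = {s: 1.0 for s in m.target.species}
        coarse = check_emulation_trajectory(m, ones, t_end=1.0, rtol=1e-8, atol=1e-8)
        fine = check_emulation_trajectory(m, ones, t_end=1.0, rtol=5e-9, atol=5e-9)
        ratio = coarse.trajectory_deviation / fine.trajectory_deviation
        assert 0.1 < ratio < 10.0


class TestSteadyStateTransfer:
    def test_boundary_steady_state_pulls_back(self, mi_to_am):
        res = steady_state_transfer(mi_to_am, {"x0": 2.0, "x1": 0.0, "x2": 0.0})
        assert res.holds
        assert res.max_residual < 1e-12

    def test_interior_fixed_point_pulls_back(self, mi_to_am, am):
        sm = am.stoich_matrices()
        from crnemu.kinetics import mass_action_vector

        def F(x):
            return sm.instantaneous @ mass_action_vector(am, np.abs(x))

        # locate the symmetric interior fixed point on the total-mass-3 simplex
        x = np.abs(fsolve(lambda x: F(x) + [sum(x) - 3.0, 0, 0], [1.1, 0.9, 1.0],
                          xtol=1e-13))
        v_hat = dict(zip(am.species, x.tolist()))
        res = steady_state_transfer(mi_to_am, v_hat, tol=1e-9)
        assert res.holds

    def test_identity_transfers_trivially(self, am):
        res = steady_state_transfer(identity_morphism(am),
                                    {"x0": 1.5, "x1": 0.0, "x2": 0.0})
        assert res.holds

    def test_non_steady_precondition_rejected(self, mi_to_am):
        with pytest.raises(CRNError, match="not steady"):
            steady_state_transfer(mi_to_am, {"x0": 1.0, "x1": 0.0, "x2": 1.0})
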