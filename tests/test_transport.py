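import numpy as np
import pytest

import capflow as cf
from capflow.hemodynamics import PressureSolver, tube_from_discharge
from capflow.transport import (
    ModelVariant,
    RBCState,
    RBCTransport,
    VesselTables,
    bifurcation_rule_choice,
    pries_split_fraction,
    rbc_velocity,
)


class TestRbcVelocity:
    def test_equal_hematocrits_give_bulk_velocity(self):
        assert rbc_velocity(1e-3, 0.3, 0.3) == pytest.approx(1e-3)

    def test_passive_particles_move_with_bulk(self):
        assert rbc_velocity(2e-3, 0.1, 0.3, ModelVariant.PASSIVE_PARTICLES) == 2e-3

    def test_fahraeus_speedup_matches_forward_law(self):
        ht = tube_from_discharge(8.0, 0.3)
        v = rbc_velocity(1e-3, ht, 0.3)
        assert v / 1e-3 == pytest.approx(0.3 / ht)
        assert v > 1e-3

    def test_never_slower_than_bulk(self):
        for d in (4.0, 8.0, 20.0):
            for hd in (0.1, 0.3, 0.5):
                ht = tube_from_discharge(d, hd)
                assert rbc_velocity(1.0, ht, hd) >= 1.0


class TestPriesSplit:
    def test_symmetric_half_split(self):
        assert pries_split_fraction(0.5, 20.0, 14.0, 14.0, 0.45) == pytest.approx(0.5)

    def test_plasma_skimming_below_threshold(self):
        # X0 = 0.4/20 = 0.02: below it no cells enter daughter 1
        assert pries_split_fraction(0.015, 20.0, 14.0, 14.0, 0.45) == 0.0
        assert pries_split_fraction(0.99, 20.0, 14.0, 14.0, 0.45) == 1.0

    def test_published_coefficients_hand_value(self):
        # A=0, B=1+6.98*0.55/20, X0=0.02, x=(0.7-0.02)/0.96
        import math

        b = 1.0 + 6.98 * 0.55 / 20.0
        x = (0.7 - 0.02) / 0.96
        expected = 1.0 / (1.0 + math.exp(-b * math.log(x / (1 - x))))
        got = pries_split_fraction(0.7, 20.0, 14.0, 14.0, 0.45)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0.7  # the high-flow daughter is RBC-enriched

    def test_daughter_swap_complement(self):
        for fqb in (0.3, 0.5, 0.65):
            a = pries_split_fraction(fqb, 18.0, 12.0, 9.0, 0.4)
            b = pries_split_fraction(1.0 - fqb, 18.0, 9.0, 12.0, 0.4)
            assert a + b == pytest.approx(1.0, abs=1e-12)


class TestBifurcationRule:
    def test_max_force_wins(self):
        rng = np.random.default_rng(0)
        assert bifurcation_rule_choice((2.0, 1.0), rng) == 0
        assert bifurcation_rule_choice((1.0, 3.0), rng) == 1

    def test_tie_broken_by_fair_coin_reproducibly(self):
        draws = [bifurcation_rule_choice((1.0, 1.0), np.random.default_rng(5))
                 for _ in range(10)]
        assert len(set(draws)) == 1  # same seed, same choice
        many = [bifurcation_rule_choice((1.0, 1.0), np.random.default_rng(k))
                for k in range(400)]
        assert 0.4 < np.mean(many) < 0.6

    def test_blocked_preferred_daughter_yields(self):
        rng = np.random.default_rng(0)
        assert bifurcation_rule_choice((2.0, 1.0), rng, blocked=[True, False]) == 1
        assert bifurcation_rule_choice((2.0, 1.0), rng, blocked=[True, True]) is None


def make_toy_70_30():
    from capflow.testing import toy_bifurcation_70_30

    return toy_bifurcation_70_30()


class TestAdvance:
    def test_unblocked_kinematics(self, toy_y):
        """A lone cell moves v_RBC dt along its vessel."""
        tab = VesselTables(toy_y, "passive_particles")
        tr = RBCTransport(toy_y, "passive_particles")
        sol = PressureSolver(toy_y)
        st = RBCState(toy_y)
        st._t[0] = [10.0]
        st._ids[0] = [st._take_id()]
        st._counts[0] = 1
        flow = sol.solve(tab.resistance(st.counts()))
        v_um = abs(flow.v_ms[0]) * 1e6
        dt = 1e-5
        tr.advance(st, flow, dt, np.random.default_rng(0), tab)
        assert st.positions_s_um(0)[0] == pytest.approx(10.0 + v_um * dt)

    def test_follower_never_overtakes_blocked_leader(self, toy_y):
        tab = VesselTables(toy_y, "with_rbcs")
        tr = RBCTransport(toy_y, "with_rbcs")
        sol = PressureSolver(toy_y)
        st = RBCState(toy_y)
        l_rbc = st.l_rbc_um[0]
        L = toy_y.length_um[0]
        # leader at the exit, follower close behind; both daughters blocked
        st._t[0] = [L - l_rbc - 0.01, L - 0.001]
        st._ids[0] = [0, 1]
        st._counts[0] = 2
        for k in (1, 2):  # pack both daughter entrances
            st._t[k] = [0.0]
            st._ids[k] = [10 + k]
            st._counts[k] = 1
        flow = sol.solve(tab.resistance(st.counts()))
        rng = np.random.default_rng(0)
        tr.advance(st, flow, 1e-5, rng, tab)
        # both entrances were at the packing limit: the leader waits at the
        # exit and the follower stacks behind at the minimum spacing
        assert st._counts[0] == 2
        assert st.min_spacing_ratio() >= 1.0 - 1e-9
        for _ in range(5):  # plug cells drift on; jam contract must hold
            tr.advance(st, flow, 1e-5, rng, tab)
        assert st.min_spacing_ratio() >= 1.0 - 1e-9

    def test_passive_split_follows_bulk_flow(self):
        """>= 5000 routed passive particles split 70/30 like the bulk flow."""
        g = make_toy_70_30()
        tab = VesselTables(g, "passive_particles")
        tr = RBCTransport(g, "passive_particles")
        sol = PressureSolver(g)
        st = RBCState(g)
        rng = np.random.default_rng(11)
        flow = sol.solve(tab.resistance(st.counts()))
        fqb = abs(flow.q_m3s[1]) / (abs(flow.q_m3s[1]) + abs(flow.q_m3s[2]))
        assert fqb == pytest.approx(0.7, abs=1e-12)
        # dilute traffic so jams stay negligible and the pure Bernoulli
        # split is what gets measured
        dt = 2e-4
        while sum(tr.routings_by_vessel.values()) < 6000:
            tr.advance(st, flow, dt, rng, tab)
            tr.inject(st, flow, dt, 0.02, rng, tab)
        n1 = tr.routings_by_vessel.get(1, 0)
        n = n1 + tr.routings_by_vessel.get(2, 0)
        se = np.sqrt(0.7 * 0.3 / n)
        assert n1 / n == pytest.approx(0.7, abs=2 * se)

    def test_ledger_exact_on_small_lattice(self):
        g = cf.generate_lattice_mvn(cf.SynthConfig(seed=2, nx=5, ny=5, nz=5))
        tab = VesselTables(g, "with_rbcs")
        tr = RBCTransport(g, "with_rbcs")
        sol = PressureSolver(g)
        st = RBCState.from_uniform_hematocrit(g, 0.3)
        n0 = st.n_rbcs
        rng = np.random.default_rng(0)
        for _ in range(400):
            flow = sol.solve(tab.resistance(st._counts))
            tr.advance(st, flow, 2e-4, rng, tab)
            tr.inject(st, flow, 2e-4, 0.3, rng, tab)
        assert st.n_rbcs == n0 + st.n_injected - st.n_ejected
        assert st.min_spacing_ratio() >= 1.0 - 1e-9


class TestInject:
    def test_zero_inflow_hematocrit_inserts_nothing(self, toy_y):
        tab = VesselTables(toy_y, "with_rbcs")
        tr = RBCTransport(toy_y, "with_rbcs")
        sol = PressureSolver(toy_y)
        st = RBCState(toy_y)
        flow = sol.solve(tab.resistance(st.counts()))
        for _ in range(100):
            tr.inject(st, flow, 1e-4, 0.0, np.random.default_rng(0), tab)
        assert st.n_rbcs == 0

    def test_long_run_insertion_rate_matches_flux(self):
        """q = 100 um^3/ms at H_in = 0.3 and V_RBC = 49 um^3 inserts
        0.612 cells/ms in the long run."""
        from capflow.graph import VascularGraph
        from capflow.hemodynamics import FlowState

        g = VascularGraph(
            node_id=[0, 1],
            pos_um=[[0, 0, 0], [1000, 0, 0]],
            is_boundary=[True, True],
            boundary_pressure_mmhg=[40.0, 10.0],
            vessel_id=[0],
            node_from=[0],
            node_to=[1],
            length_um=[1000.0],
            diameter_um=[10.0],
            vtype=["capillary"],
        ).validate()
        tr = RBCTransport(g, "with_rbcs")
        tab = VesselTables(g, "with_rbcs")
        st = RBCState(g)
        q = 100e3 * 1e-18  # 100 um^3/ms in m^3/s
        area = g.cross_section_um2()[0] * 1e-12
        flow = FlowState(
            pressures_pa=np.zeros(2),
            q_m3s=np.array([q]),
            v_ms=np.array([q / area]),
            resistance=np.array([1e15]),
        )
        rng = np.random.default_rng(0)
        dt = 1e-3  # 1 ms steps
        n_steps = 20000
        for _ in range(n_steps):
            tr.advance(st, flow, dt, rng, tab)
            tr.inject(st, flow, dt, 0.3, rng, tab)
        rate_per_ms = st.n_injected / n_steps
        assert rate_per_ms == pytest.approx(0.612, abs=0.01)

    def test_blocked_inlet_defers_but_preserves_rate(self, toy_y):
        tab = VesselTables(toy_y, "with_rbcs")
        tr = RBCTransport(toy_y, "with_rbcs")
        sol = PressureSolver(toy_y)
        st = RBCState(toy_y)
        flow = sol.solve(tab.resistance(st.counts()))
        # plug the inlet entrance
        st._t[0] = [0.0]
        st._ids[0] = [st._take_id()]
        st._counts[0] = 1
        rng = np.random.default_rng(0)
        for _ in range(50):
            tr.inject(st, flow, 1e-5, 0.3, rng, tab)
        assert st.n_injected == 0
        assert tr._inject_acc[0] > 1.0  # deficit carried forward
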