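import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capflow as cf
from capflow.hemodynamics import (
    PressureSolver,
    discharge_from_tube,
    effective_resistance,
    plasma_resistance,
    relative_apparent_viscosity,
    solve_pressures,
    tube_from_discharge,
)
from capflow.testing import dense_pressure_oracle, random_tree_graph


class TestPlasmaResistance:
    def test_closed_form_value(self):
        # 128 mu L / (pi D^4) at L=100 um, D=8 um, mu=1.2e-3 Pa s
        assert plasma_resistance(100e-6, 8e-6, 1.2e-3) == pytest.approx(
            1.19366207319e15, rel=1e-4
        )

    def test_diameter_and_length_scaling(self):
        r = plasma_resistance(100e-6, 8e-6)
        assert plasma_resistance(100e-6, 16e-6) == pytest.approx(r / 16)
        assert plasma_resistance(200e-6, 8e-6) == pytest.approx(2 * r)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            plasma_resistance(-1e-6, 8e-6)
        with pytest.raises(ValueError):
            plasma_resistance(1e-6, 0.0)


class TestViscosityLaw:
    def test_pure_plasma_is_unity(self):
        for d in (3.0, 7.0, 10.0, 50.0, 300.0):
            assert relative_apparent_viscosity(d, 0.0) == pytest.approx(1.0)

    def test_diameter_minimum_near_seven_um(self):
        # the Fahraeus-Lindqvist minimum sits near 7 um, far below the
        # large-tube plateau
        assert relative_apparent_viscosity(7.0, 0.45) < relative_apparent_viscosity(
            50.0, 0.45
        )
        assert not (
            relative_apparent_viscosity(10.0, 0.45)
            > relative_apparent_viscosity(100.0, 0.45)
        )

    def test_monotone_in_hematocrit(self):
        grid = np.linspace(0.0, 0.6, 25)
        eta = relative_apparent_viscosity(6.0, grid)
        assert np.all(np.diff(eta) > 0)
        assert np.all(eta >= 1.0)

    def test_out_of_range_hematocrit_rejected(self):
        with pytest.raises(ValueError):
            relative_apparent_viscosity(8.0, 1.0)


class TestEffectiveResistance:
    def test_zero_hematocrit_reduces_to_plasma(self):
        assert effective_resistance(100e-6, 8e-6, 0.0) == pytest.approx(
            plasma_resistance(100e-6, 8e-6), rel=1e-14
        )

    def test_product_decomposition(self):
        r = effective_resistance(100e-6, 8e-6, 0.45)
        assert r == pytest.approx(
            plasma_resistance(100e-6, 8e-6) * relative_apparent_viscosity(8.0, 0.45)
        )
        assert r >= plasma_resistance(100e-6, 8e-6)


class TestFahraeusRelation:
    def test_fixed_points(self):
        assert tube_from_discharge(8.0, 0.0) == 0.0
        assert tube_from_discharge(8.0, 1.0) == 1.0
        assert discharge_from_tube(8.0, 0.0) == 0.0
        assert discharge_from_tube(8.0, 1.0) == 1.0

    def test_tube_below_discharge(self):
        for d in (4.0, 8.0, 20.0):
            for h in (0.1, 0.3, 0.6, 0.9):
                assert tube_from_discharge(d, h) <= h

    def test_large_vessel_limit(self):
        assert tube_from_discharge(1000.0, 0.45) == pytest.approx(0.45, abs=1e-3)

    def test_inverse_round_trip(self):
        ht = tube_from_discharge(8.0, 0.3)
        assert ht < 0.3
        assert discharge_from_tube(8.0, ht) == pytest.approx(0.3, abs=1e-10)

    @given(st.floats(min_value=0.01, max_value=0.95),
           st.floats(min_value=3.0, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, h_d, d):
        ht = tube_from_discharge(d, h_d)
        assert discharge_from_tube(d, ht) == pytest.approx(h_d, abs=1e-9)


class TestPressureSolve:
    def test_path_symmetry(self):
        # A-B-C with equal resistances: the interior pressure is the average
        from .test_graph import path_graph

        g = path_graph()
        r = np.array([1e15, 1e15])
        fs = solve_pressures(g, r)
        from capflow.units import mmhg_to_pa

        assert fs.pressures_pa[1] == pytest.approx(mmhg_to_pa(30.0))
        assert fs.q_m3s[0] == pytest.approx(fs.q_m3s[1])

    def test_symmetric_y_splits_evenly(self, toy_y):
        r = effective_resistance(toy_y.length_um * 1e-6, toy_y.diameter_um * 1e-6, 0.0)
        fs = solve_pressures(toy_y, r)
        assert fs.q_m3s[1] == pytest.approx(fs.q_m3s[2])
        assert fs.q_m3s[0] == pytest.approx(fs.q_m3s[1] + fs.q_m3s[2])

    def test_daughter_flows_scale_with_d4_under_plasma(self):
        g = cf.generate_toy_bifurcation(8.0, 6.0, 4.0, 100.0, 40.0, 10.0, 10.0)
        r = effective_resistance(g.length_um * 1e-6, g.diameter_um * 1e-6, 0.0)
        fs = solve_pressures(g, r)
        # both daughters see the same junction-to-outlet pressure drop
        assert fs.q_m3s[1] / fs.q_m3s[2] == pytest.approx((6.0 / 4.0) ** 4)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = random_tree_graph(rng, n_nodes=int(rng.integers(8, 30)))
            r = rng.uniform(1e13, 1e16, size=g.n_vessels)
            fs = solve_pressures(g, r)
            p_ref = dense_pressure_oracle(g, r)
            assert np.max(np.abs(fs.pressures_pa - p_ref)) <= 1e-10 * np.max(
                np.abs(p_ref)
            )

    def test_interior_mass_balance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_tree_graph(rng, n_nodes=25)
            r = rng.uniform(1e13, 1e16, size=g.n_vessels)
            fs = solve_pressures(g, r)
            res = np.zeros(g.n_nodes)
            np.add.at(res, g.node_from_idx, -fs.q_m3s)
            np.add.at(res, g.node_to_idx, fs.q_m3s)
            assert np.max(np.abs(res[~g.is_boundary])) <= 1e-10 * np.max(
                np.abs(fs.q_m3s)
            )

    def test_dilating_a_vessel_never_reduces_its_flow(self):
        rng = np.random.default_rng(3)
        g = random_tree_graph(rng, n_nodes=20)
        r = effective_resistance(g.length_um * 1e-6, g.diameter_um * 1e-6, 0.0)
        fs = solve_pressures(g, r)
        for j in range(0, g.n_vessels, 3):
            d2 = g.diameter_um.copy()
            d2[j] *= 1.2
            r2 = effective_resistance(g.length_um * 1e-6, d2 * 1e-6, 0.0)
            fs2 = solve_pressures(g, r2)
            assert abs(fs2.q_m3s[j]) >= abs(fs.q_m3s[j]) * (1 - 1e-12)

    def test_isolated_vessel_dilation_closed_form(self):
        """A uniformly dilated single vessel carries flow x f^4 (pure plasma)."""
        from capflow.graph import VascularGraph

        def single(d_um):
            return VascularGraph(
                node_id=[0, 1],
                pos_um=[[0, 0, 0], [100, 0, 0]],
                is_boundary=[True, True],
                boundary_pressure_mmhg=[40.0, 10.0],
                vessel_id=[0],
                node_from=[0],
                node_to=[1],
                length_um=[100.0],
                diameter_um=[d_um],
                vtype=["capillary"],
            ).validate()

        q = []
        for d in (8.0, 8.0 * 1.1):
            g = single(d)
            r = effective_resistance(g.length_um * 1e-6, g.diameter_um * 1e-6, 0.0)
            q.append(solve_pressures(g, r).q_m3s[0])
        assert q[1] / q[0] == pytest.approx(1.1**4, abs=1e-12)

    def test_singular_system_raises(self):
        from capflow.graph import VascularGraph
        from capflow.hemodynamics import GraphTopologyError

        # two boundary nodes but zero-conductance cut is impossible; instead
        # build an interior cycle attached to no boundary: validation itself
        # rejects it, so test the solver by passing infinite resistance
        g = cf.generate_toy_bifurcation(8.0, 6.0, 6.0, 100.0, 40.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            PressureSolver(g).solve([np.inf, 1e15, 1e15])
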