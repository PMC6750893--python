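import numpy as np
import pandas as pd
import pytest

import capflow as cf
from capflow.graph import (
    GraphFormatError,
    GraphIntegrityError,
    VascularGraph,
    generations_up_downstream,
    read_graph,
    write_graph,
)


def path_graph():
    return VascularGraph(
        node_id=[0, 1, 2],
        pos_um=[[0, 0, 0], [100, 0, 0], [200, 0, 0]],
        is_boundary=[True, False, True],
        boundary_pressure_mmhg=[50.0, np.nan, 10.0],
        vessel_id=[0, 1],
        node_from=[0, 1],
        node_to=[1, 2],
        length_um=[100.0, 100.0],
        diameter_um=[8.0, 8.0],
        vtype=["capillary", "capillary"],
    ).validate()


class TestRoundTrip:
    def test_path_graph_round_trip(self, tmp_path):
        g = path_graph()
        write_graph(g, tmp_path / "n.csv", tmp_path / "v.csv")
        g2 = read_graph(tmp_path / "n.csv", tmp_path / "v.csv")
        assert g.equals(g2)

    def test_lattice_round_trip(self, tmp_path):
        g = cf.generate_lattice_mvn(cf.SynthConfig(seed=1, nx=4, ny=4, nz=4))
        write_graph(g, tmp_path / "n.csv", tmp_path / "v.csv")
        assert g.equals(read_graph(tmp_path / "n.csv", tmp_path / "v.csv"))

    def test_dangling_node_reference_rejected(self, tmp_path):
        g = path_graph()
        nodes, vessels = g.to_frames()
        vessels.loc[1, "node_to"] = 99
        nodes.to_csv(tmp_path / "n.csv", index=False)
        vessels.to_csv(tmp_path / "v.csv", index=False)
        with pytest.raises(GraphIntegrityError, match="99"):
            read_graph(tmp_path / "n.csv", tmp_path / "v.csv")

    def test_missing_column_rejected(self, tmp_path):
        g = path_graph()
        nodes, vessels = g.to_frames()
        vessels.drop(columns=["diameter_um"]).to_csv(tmp_path / "v.csv", index=False)
        nodes.to_csv(tmp_path / "n.csv", index=False)
        with pytest.raises(GraphFormatError, match="diameter_um"):
            read_graph(tmp_path / "n.csv", tmp_path / "v.csv")


class TestValidation:
    """Every mutation that breaks a stated invariant must be rejected."""

    @pytest.mark.parametrize(
        "mutate, exc",
        [
            (lambda n, v: v.loc.__setitem__((0, "length_um"), -5.0), ValueError),
            (lambda n, v: v.loc.__setitem__((0, "diameter_um"), 0.0), ValueError),
            (lambda n, v: v.loc.__setitem__((0, "length_um"), 10.0), ValueError),
            (lambda n, v: v.loc.__setitem__((0, "node_to"), 0), GraphIntegrityError),
            (lambda n, v: v.loc.__setitem__((0, "type"), "vein"), GraphFormatError),
            (lambda n, v: n.loc.__setitem__((1, "x_um"), np.inf), ValueError),
            (lambda n, v: n.loc.__setitem__((0, "boundary_pressure_mmHg"), np.nan),
             GraphFormatError),
        ],
    )
    def test_broken_invariant_rejected(self, mutate, exc):
        nodes, vessels = path_graph().to_frames()
        nodes = nodes.set_index(pd.RangeIndex(len(nodes)))
        mutate(nodes, vessels)
        with pytest.raises(exc):
            VascularGraph.from_frames(nodes, vessels)

    def test_boundary_node_degree_enforced(self):
        nodes, vessels = path_graph().to_frames()
        nodes.loc[1, "is_boundary"] = 1
        nodes.loc[1, "boundary_pressure_mmHg"] = 30.0
        with pytest.raises(GraphIntegrityError, match="degree"):
            VascularGraph.from_frames(nodes, vessels)

    def test_disconnected_rejected(self):
        g = path_graph()
        nodes, vessels = g.to_frames()
        extra_nodes = pd.DataFrame(
            {
                "node_id": [10, 11],
                "x_um": [500.0, 600.0],
                "y_um": [0.0, 0.0],
                "z_um": [0.0, 0.0],
                "is_boundary": [1, 1],
                "boundary_pressure_mmHg": [20.0, 10.0],
            }
        )
        extra_vessels = pd.DataFrame(
            {
                "vessel_id": [10],
                "node_from": [10],
                "node_to": [11],
                "length_um": [100.0],
                "diameter_um": [5.0],
                "type": ["capillary"],
            }
        )
        with pytest.raises(GraphIntegrityError, match="connected"):
            VascularGraph.from_frames(
                pd.concat([nodes, extra_nodes], ignore_index=True),
                pd.concat([vessels, extra_vessels], ignore_index=True),
            )


class TestGenerations:
    def make_tree(self):
        """Binary tree: inflow -> root bifurcation -> two daughters -> leaves."""
        #        0 (in)
        #        |
        #        1  <- site
        #       / \
        #      2   3
        #     /|   |\
        #    4 5   6 7
        pos = np.array(
            [
                [0, 0, 0],
                [0, 0, 100],
                [-80, 0, 160],
                [80, 0, 160],
                [-120, 0, 250],
                [-40, 0, 250],
                [40, 0, 250],
                [120, 0, 250],
            ],
            dtype=float,
        )
        edges = [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7)]
        length = [110.0, 110.0, 110.0, 110.0, 110.0, 110.0, 110.0]
        is_b = np.array([True, False, False, False, True, True, True, True])
        bp = np.where(is_b, [50, 0, 0, 0, 10, 10, 10, 10], np.nan)
        return VascularGraph(
            node_id=np.arange(8),
            pos_um=pos,
            is_boundary=is_b,
            boundary_pressure_mmhg=bp,
            vessel_id=np.arange(7),
            node_from=[e[0] for e in edges],
            node_to=[e[1] for e in edges],
            length_um=length,
            diameter_um=[8.0] * 7,
            vtype=["capillary"] * 7,
        ).validate()

    def test_tree_generations_hand_enumerated(self):
        g = self.make_tree()
        direction = np.ones(7)  # all flows follow storage orientation
        gens = generations_up_downstream(g, direction, site=1, n=2)
        assert gens[1] == {3, 4, 5, 6}   # children of both daughters
        assert gens[-1] == set()         # inflow vessel is generation 0 (mother)
        assert gens[2] == set()          # leaves reached, nothing further

    def test_generation_sets_disjoint_and_exclude_site(self, reference_run_rbc,
                                                       reference_lattice):
        g = reference_lattice
        field = reference_run_rbc.field
        bs = cf.classify_bifurcations(g, field)
        inc = g.incident_vessels()
        for rec in bs.divergent[:10]:
            gens = generations_up_downstream(g, field, rec.node_id, 3)
            site_vessels = {
                int(g.vessel_id[j]) for j in inc[g.node_index(rec.node_id)]
            }
            seen = set()
            for s in gens.values():
                assert not (s & site_vessels)
                assert not (s & seen)
                seen |= s

    def test_generations_match_directed_bfs_oracle(self, reference_run_rbc,
                                                   reference_lattice):
        """Generation I sets equal a breadth-first walk on the flow digraph."""
        g = reference_lattice
        field = reference_run_rbc.field
        bs = cf.classify_bifurcations(g, field)
        direction = field.direction
        inc = g.incident_vessels()
        for rec in bs.divergent[:10]:
            gens = generations_up_downstream(g, field, rec.node_id, 1)
            node = g.node_index(rec.node_id)
            # oracle: vessels delivering flow into the mother's tail node
            mother = [j for j in inc[node]
                      if direction[j] != 0
                      and (g.node_to_idx[j] if direction[j] > 0 else g.node_from_idx[j]) == node]
            up = set()
            for m in mother:
                tail = g.node_from_idx[m] if direction[m] > 0 else g.node_to_idx[m]
                for j in inc[tail]:
                    if j in inc[node] or direction[j] == 0:
                        continue
                    head = g.node_to_idx[j] if direction[j] > 0 else g.node_from_idx[j]
                    if head == tail:
                        up.add(int(g.vessel_id[j]))
            assert gens[-1] == up
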