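"""Synthetic fixtures and independent oracles used by the test suite and
the acceptance script.

These deliberately avoid the package's own solver paths: the dense oracle
builds and solves the full nodal matrix with ``numpy.linalg``.
"""

from __future__ import annotations

import numpy as np

from .graph import VascularGraph
from .units import mmhg_to_pa


def random_tree_graph(rng, n_nodes=20, extra_edges=3):
    """Random connected vascular graph whose leaves are boundary nodes.

    Random spanning tree plus a few extra interior edges; every leaf gets a
    boundary pressure.  The substrate for solver-oracle tests.
    """
    parents = [int(rng.integers(0, i)) for i in range(1, n_nodes)]
    edges = [(p, i) for i, p in enumerate(parents, start=1)]
    deg = np.zeros(n_nodes, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    interior = np.flatnonzero(deg >= 2)
    tries = 0
    while extra_edges > 0 and tries < 50 and len(interior) >= 2:
        a, b = rng.choice(interior, size=2, replace=False)
        if a != b and (a, b) not in edges and (b, a) not in edges:
            edges.append((int(a), int(b)))
            extra_edges -= 1
        tries += 1
    deg = np.zeros(n_nodes, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    is_boundary = deg == 1

    pos = rng.uniform(0, 500, size=(n_nodes, 3))
    length = np.array(
        [np.linalg.norm(pos[a] - pos[b]) * (1 + rng.uniform(0, 0.3)) for a, b in edges]
    )
    diam = rng.uniform(3, 12, size=len(edges))
    bp = np.where(is_boundary, rng.uniform(10, 60, size=n_nodes), np.nan)
    return VascularGraph(
        node_id=np.arange(n_nodes),
        pos_um=pos,
        is_boundary=is_boundary,
        boundary_pressure_mmhg=bp,
        vessel_id=np.arange(len(edges)),
        node_from=np.array([a for a, _ in edges]),
        node_to=np.array([b for _, b in edges]),
        length_um=length,
        diameter_um=diam,
        vtype=np.array(["capillary"] * len(edges), dtype=object),
    ).validate()


def dense_pressure_oracle(graph, resistance):
    """Full-matrix reference solve of the nodal system (mmHg boundaries)."""
    n = graph.n_nodes
    a = np.zeros((n, n))
    b = np.zeros(n)
    cond = 1.0 / np.asarray(resistance)
    for j in range(graph.n_vessels):
        i1, i2 = graph.node_from_idx[j], graph.node_to_idx[j]
        a[i1, i1] += cond[j]
        a[i2, i2] += cond[j]
        a[i1, i2] -= cond[j]
        a[i2, i1] -= cond[j]
    for i in range(n):
        if graph.is_boundary[i]:
            a[i, :] = 0.0
            a[i, i] = 1.0
            b[i] = mmhg_to_pa(graph.boundary_pressure_mmhg[i])
    return np.linalg.solve(a, b)


def toy_bifurcation_70_30():
    """Toy divergent bifurcation whose plasma bulk split is exactly 70/30.

    Equal daughter diameters and outlet pressures; daughter 2 is lengthened
    so R2/R1 = 7/3 (flow ratio 70/30 under a common pressure drop).
    """
    L1, L2 = 100.0, 100.0 * 7.0 / 3.0
    pos = np.array(
        [[0, 0, 0], [100, 0, 0], [200, 0, 0], [100 + L2 * 0.8, L2 * 0.6, 0]],
        dtype=float,
    )
    return VascularGraph(
        node_id=np.arange(4),
        pos_um=pos,
        is_boundary=[True, False, True, True],
        boundary_pressure_mmhg=[40.0, np.nan, 10.0, 10.0],
        vessel_id=np.arange(3),
        node_from=[0, 1, 1],
        node_to=[1, 2, 3],
        length_um=[100.0, L1, L2],
        diameter_um=[8.0, 6.0, 6.0],
        vtype=["capillary"] * 3,
    ).validate()
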