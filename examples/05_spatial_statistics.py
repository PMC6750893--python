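"""Spatial statistics of well-balanced bifurcations.

Assigns bifurcations to 200-um cortical analysis layers, measures nearest-
neighbour and penetrating-vessel distances, and rasterizes the tissue into
a cube grid to ask how far any tissue point is from the outflow vessel of
a well-balanced bifurcation.

Expect a couple of minutes of wall time (one steady-state run).
"""

import numpy as np

import capflow as cf
from capflow.bifurcations import BalanceClass
from capflow.spatial import (
    assign_layers,
    min_euclidean_distances,
    min_path_length_to_penetrating,
    tissue_distance_grid,
    wb_fraction_per_layer,
)

graph = cf.generate_lattice_mvn(cf.SynthConfig(seed=1))
res = cf.run_simulation(graph, cf.SimulationConfig(seed=1))
bs = cf.classify_bifurcations(graph, res.field)

div = bs.divergent
depths = np.array([graph.pos_um[graph.node_index(r.node_id), 2] for r in div])
wb = np.array([r.balance == BalanceClass.WELL_BALANCED for r in div])
layers = assign_layers(depths)
frac, cv = wb_fraction_per_layer(wb, layers)
print("well-balanced fraction per 200-um analysis layer:",
      np.round(frac, 2), f"(CV {cv:.2f})")

wb_points = np.array([graph.pos_um[graph.node_index(r.node_id)]
                      for r, w in zip(div, wb) if w])
if len(wb_points) >= 2:
    print(f"median nearest-neighbour distance between well-balanced "
          f"bifurcations: {np.median(min_euclidean_distances(wb_points)):.0f} um")

paths = [min_path_length_to_penetrating(graph, res.field, r.node_id,
                                        "descending_arteriole")
         for r, w in zip(div, wb) if w]
finite = [p for p in paths if np.isfinite(p)]
print(f"median flow-path length to the feeding arteriole: "
      f"{np.median(finite):.0f} um ({len(finite)}/{len(paths)} reachable)")

wb_out = sorted({v for r, w in zip(div, wb) if w for v in r.daughter_vessels})
grid = tissue_distance_grid(graph, wb_out, dims=(40, 40, 40))
print(f"tissue grid ({grid.n_centres} cubes): median distance to the nearest "
      f"well-balanced outflow vessel {grid.median_distance_um:.1f} um; "
      f"{grid.fraction_within_radius():.0%} of tissue within 50 um")
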