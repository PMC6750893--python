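"""Generate a synthetic cortical microvascular network and inspect it.

The generator emulates the statistical structure of the cortical capillary
bed: a jittered ~50 um mesh thinned to mean degree ~3, descending
arterioles (DA) feeding it from the surface and ascending venules (AV)
draining it, capillary diameters lognormal around 4 um and strictly below
10 um.
"""

import numpy as np

import capflow as cf

config = cf.SynthConfig(seed=1)  # 7 x 7 x 7 mesh, 2 DA + 2 AV trunks
graph = cf.generate_lattice_mvn(config)

is_cap = graph.vtype == "capillary"
deg = graph.degrees()
print(f"nodes: {graph.n_nodes}, vessels: {graph.n_vessels}")
print(f"capillary fraction: {np.mean(is_cap):.2%}")
print(f"capillary diameters: median {np.median(graph.diameter_um[is_cap]):.2f} um, "
      f"range ({graph.diameter_um[is_cap].min():.2f}, "
      f"{graph.diameter_um[is_cap].max():.2f}) um")
print(f"degree-3 interior nodes (potential bifurcations): "
      f"{int(np.sum(~graph.is_boundary & (deg == 3)))}")

# round-trip through the documented CSV pair
cf.write_graph(graph, "/tmp/nodes.csv", "/tmp/vessels.csv")
again = cf.read_graph("/tmp/nodes.csv", "/tmp/vessels.csv")
print("CSV round trip identical:", graph.equals(again))
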