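"""Solve the pressure field of a toy capillary bifurcation.

Builds a four-node Y graph (one mother, two daughters), computes pure
plasma and hematocrit-adjusted effective resistances, and solves the nodal
mass-balance system for pressures and flows.
"""

import numpy as np

import capflow as cf

# 8 um mother feeding two 6 um daughters, 100 um segments,
# 40 mmHg inlet and 10 mmHg outlets
graph = cf.generate_toy_bifurcation(8.0, 6.0, 6.0, 100.0, 40.0, 10.0, 10.0)

for h_d in (0.0, 0.3):
    resistance = cf.effective_resistance(
        graph.length_um * 1e-6, graph.diameter_um * 1e-6, h_d
    )
    flow = cf.solve_pressures(graph, resistance)
    v_mm_s = np.abs(flow.v_ms) * 1e3
    print(f"discharge hematocrit {h_d:.1f}:")
    print(f"  mother velocity   {v_mm_s[0]:6.2f} mm/s")
    print(f"  daughter velocities {v_mm_s[1]:6.2f} / {v_mm_s[2]:6.2f} mm/s")

# The daughters split the mother flow exactly in half (symmetry), and the
# hematocrit-laden run is slower everywhere: red cells raise the apparent
# viscosity (Fahraeus-Lindqvist effect), here by the same factor in every
# vessel, so the split stays 50/50.
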