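"""Spatial statistics of well-balanced bifurcations.

Where are well-balanced bifurcations in the tissue?  The analyses slice
the cortex into 200-um-thick analysis layers by depth, measure Euclidean
and flow-path distances from well-balanced bifurcations to the penetrating
vessels (descending arterioles upstream, ascending venules downstream),
and rasterize the tissue into a grid of cubes to ask how far any tissue
point is from the outflow vessel of a well-balanced bifurcation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

LAYER_THICKNESS_UM = 200.0
N_LAYERS = 5


@dataclass
class AnalysisLayers:
    """Half-open depth layers [k*t, (k+1)*t) and the per-item assignment."""

    n_layers: int
    thickness_um: float
    layer_index: np.ndarray      # -1 for out-of-range items
    n_excluded: int


def assign_layers(depths_um, n_layers=N_LAYERS, thickness_um=LAYER_THICKNESS_UM):
    """Assign each depth to its layer: index = floor(depth / thickness).

    Depth 0 is the pial surface; a depth exactly on a boundary belongs to
    the deeper layer (half-open convention).  Out-of-range depths are
    excluded and counted.
    """
    d = np.asarray(depths_um, dtype=float)
    idx = np.floor(d / thickness_um).astype(int)
    out = (d < 0) | (idx >= n_layers)
    idx = np.where(out, -1, idx)
    return AnalysisLayers(n_layers, thickness_um, idx, int(out.sum()))


def wb_fraction_per_layer(is_well_balanced, layers: AnalysisLayers):
    """Fraction of well-balanced bifurcations per layer and the CV across layers.

    Layers without any bifurcation are excluded (fraction NaN) with the CV
    computed over the populated layers only.
    """
    wb = np.asarray(is_well_balanced, dtype=bool)
    frac = np.full(layers.n_layers, np.nan)
    for k in range(layers.n_layers):
        sel = layers.layer_index == k
        if sel.any():
            frac[k] = wb[sel].mean()
    pop = frac[np.isfinite(frac)]
    cv = float(pop.std(ddof=0) / pop.mean()) if len(pop) and pop.mean() > 0 else np.nan
    return frac, cv


def min_euclidean_distances(points_a, points_b=None):
    """Per-point-of-a minimum Euclidean distance to b (um).

    With ``points_b=None`` the self-distance is computed: each point's own
    entry is excluded, returning the distance to its nearest neighbour.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    if points_b is None:
        if len(a) < 2:
            raise ValueError("self-distance needs at least two points")
        d, _ = cKDTree(a).query(a, k=2)
        return d[:, 1]
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(b) == 0:
        raise ValueError("target point set is empty")
    d, _ = cKDTree(b).query(a, k=1)
    return d


def penetrating_main_branch(graph, target_type):
    """Vessel indices of the main branches of DA or AV trunks.

    A main branch starts at the boundary (pial) end of a same-type
    component and follows same-type vessels with non-increasing diameter,
    preferring the larger diameter on ties.
    """
    tmask = graph.vtype.astype(str) == target_type
    inc = graph.incident_vessels()
    branches = []
    starts = [
        j for j in np.flatnonzero(tmask)
        if graph.is_boundary[graph.node_from_idx[j]] or graph.is_boundary[graph.node_to_idx[j]]
    ]
    for j0 in starts:
        branch = [j0]
        node = (
            graph.node_to_idx[j0]
            if graph.is_boundary[graph.node_from_idx[j0]]
            else graph.node_from_idx[j0]
        )
        cur_d = graph.diameter_um[j0]
        visited = {j0}
        while True:
            cands = [
                k for k in inc[node]
                if tmask[k] and k not in visited and graph.diameter_um[k] <= cur_d + 1e-9
            ]
            if not cands:
                break
            k = max(cands, key=lambda c: graph.diameter_um[c])
            branch.append(k)
            visited.add(k)
            node = (
                graph.node_to_idx[k]
                if graph.node_from_idx[k] == node
                else graph.node_from_idx[k]
            )
            cur_d = graph.diameter_um[k]
        branches.append(branch)
    return branches


def polyline_points(graph, vessel_indices, step_um=1.0):
    """Dense sample points along the given vessels (straight segments)."""
    pts = []
    for j in vessel_indices:
        p0 = graph.pos_um[graph.node_from_idx[j]]
        p1 = graph.pos_um[graph.node_to_idx[j]]
        n = max(int(np.ceil(np.linalg.norm(p1 - p0) / step_um)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        pts.append(p0 + t * (p1 - p0))
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def min_path_length_to_penetrating(graph, field, node_id, target_type):
    """Minimum flow-path length (um) from a bifurcation to a DA or AV.

    Walks upstream (against the flow) for descending arterioles and
    downstream for ascending venules, accumulating vessel lengths until
    the first vessel of the target type; that vessel's own length is not
    counted.  Returns +inf if the target is unreachable.
    """
    if target_type == "descending_arteriole":
        upstream = True
    elif target_type == "ascending_venule":
        upstream = False
    else:
        raise ValueError("target type must be a penetrating vessel type")
    direction = field.direction
    tmask = graph.vtype.astype(str) == target_type
    inc = graph.incident_vessels()
    start = graph.node_index(node_id)

    dist = {start: 0.0}
    heap = [(0.0, start)]
    while heap:
        d, node = heapq.heappop(heap)
        if d > dist.get(node, np.inf):
            continue
        for j in inc[node]:
            dirn = direction[j]
            if dirn == 0:
                continue
            head = graph.node_to_idx[j] if dirn > 0 else graph.node_from_idx[j]
            tail = graph.node_from_idx[j] if dirn > 0 else graph.node_to_idx[j]
            # upstream walk traverses vessels whose flow arrives at `node`
            if upstream and head != node:
                continue
            if not upstream and tail != node:
                continue
            if tmask[j]:
                return d
            nxt = tail if upstream else head
            nd = d + float(graph.length_um[j])
            if nd < dist.get(nxt, np.inf):
                dist[nxt] = nd
                heapq.heappush(heap, (nd, nxt))
    return np.inf


@dataclass
class TissueGrid:
    dims: tuple
    centres_um: np.ndarray       # (gx*gy*gz, 3)
    distances_um: np.ndarray     # (gx*gy*gz,)
    radius_um: float

    @property
    def n_centres(self) -> int:
        return int(np.prod(self.dims))

    @property
    def median_distance_um(self) -> float:
        return float(np.median(self.distances_um))

    def fraction_within_radius(self, radius_um=None) -> float:
        r = self.radius_um if radius_um is None else radius_um
        return float(np.mean(self.distances_um <= r))

    def to_frame(self):
        import pandas as pd

        gx, gy, gz = self.dims
        ix, iy, iz = np.unravel_index(np.arange(self.n_centres), (gx, gy, gz))
        return pd.DataFrame(
            {"ix": ix, "iy": iy, "iz": iz, "distance_um": self.distances_um}
        )


def _point_segment_distances(points, p0, p1):
    """Min distance from each point to each segment; returns (n_points,) min."""
    seg = p1 - p0                                     # (m, 3)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)        # (m,)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1.0)
    best = np.full(len(points), np.inf)
    for k in range(len(p0)):                          # few segments, many points
        w = points - p0[k]
        t = np.clip(w @ seg[k] / seg_len2[k], 0.0, 1.0)
        proj = p0[k] + t[:, None] * seg[k]
        d = np.linalg.norm(points - proj, axis=1)
        best = np.minimum(best, d)
    return best


def tissue_distance_grid(graph, wb_outflow_vessel_ids, dims, radius_um=50.0) -> TissueGrid:
    """Distance from every tissue-cube centre to the nearest well-balanced
    outflow vessel (exact point-to-segment geometry).

    The domain is the graph's bounding box divided into ``dims`` cubes;
    the default 50 um influence radius is the mean inter-capillary
    distance of the cortical bed.
    """
    ids = list(wb_outflow_vessel_ids)
    if not ids:
        raise ValueError("no well-balanced outflow vessels supplied")
    gx, gy, gz = dims
    if min(dims) <= 0:
        raise ValueError("grid dims must be positive")
    lo = graph.pos_um.min(axis=0)
    hi = graph.pos_um.max(axis=0)
    edges = (hi - lo) / np.array([gx, gy, gz], dtype=float)
    ix, iy, iz = np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij")
    centres = lo + (np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) + 0.5) * edges

    j = np.array([graph.vessel_index(v) for v in ids])
    p0 = graph.pos_um[graph.node_from_idx[j]]
    p1 = graph.pos_um[graph.node_to_idx[j]]
    d = _point_segment_distances(centres, p0, p1)
    return TissueGrid(dims=(gx, gy, gz), centres_um=centres, distances_um=d,
                      radius_um=radius_um)
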