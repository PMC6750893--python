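"""Seeded generator of synthetic cortical microvascular networks.

Real cortical capillary beds form an interconnected mesh with a mean
inter-capillary distance of ~50 um, on average a handful of capillary
segments between arteriole and venule, capillary diameters below 10 um,
and penetrating descending arterioles (DA) feeding the mesh from the pial
surface while ascending venules (AV) drain it.  The generator emulates that
statistical structure on a jittered cubic lattice:

1. capillary nodes sit on a jittered nx x ny x nz grid (z is cortical
   depth, 0 at the pial surface);
2. the full 6-neighbour adjacency is thinned by random removal of
   non-bridge edges until the mean degree is ~3, which creates the
   degree-3 capillary bifurcations all analyses run on while keeping the
   mesh connected and every interior node at degree >= 2;
3. DA and AV trunks descend vertically at interior columns and attach to
   the mesh through one capillary offshoot per depth level; only the trunk
   tops are boundary nodes, carrying the inlet/outlet pressures.

Everything is drawn from a single ``numpy`` generator seeded from the
config, so the same config yields byte-identical CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .graph import VascularGraph


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic lattice network.

    Defaults encode the study conditions: 50 um capillary spacing, capillary
    diameters lognormal(median 4 um, geometric sd 1.2) truncated to
    (2, 9.9) um so the whole bed stays in the bifurcation-rule regime,
    15 um penetrating trunks, and fixed inlet/outlet pressures.
    """

    seed: int = 0
    nx: int = 7
    ny: int = 7
    nz: int = 7
    spacing_um: float = 50.0
    cap_diameter_median_um: float = 4.0
    cap_diameter_gsd: float = 1.2
    cap_diameter_min_um: float = 2.0
    cap_diameter_max_um: float = 9.9
    trunk_diameter_um: float = 15.0
    n_da: int = 2
    n_av: int = 2
    jitter: float = 0.2
    p_inlet_mmhg: float = 60.0
    p_outlet_mmhg: float = 10.0
    depth_um: float = 1000.0
    mean_degree: float = 3.0
    #: neighbour-averaging sweeps of the lognormal diameter field; capillary
    #: diameters in real cortex vary smoothly in space, so sibling daughters
    #: have similar calibres (0 = independent per-vessel draws)
    diameter_smoothing_sweeps: int = 3

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("lattice dimensions must be >= 3 in each direction")
        for name in (
            "spacing_um",
            "cap_diameter_median_um",
            "trunk_diameter_um",
            "depth_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.cap_diameter_min_um < self.cap_diameter_max_um < 10.0):
            raise ValueError("capillary diameters must stay strictly below 10 um")
        if self.jitter < 0 or self.jitter >= 0.5:
            raise ValueError("jitter must lie in [0, 0.5)")
        if self.p_inlet_mmhg <= self.p_outlet_mmhg:
            raise ValueError("inlet pressure must exceed outlet pressure")
        if self.nz * self.spacing_um > self.depth_um:
            raise ValueError("lattice is deeper than the stated cortical depth")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_capillary_diameters(rng, n, cfg: SynthConfig):
    """Truncated lognormal capillary diameters, resampled until in range."""
    mu = np.log(cfg.cap_diameter_median_um)
    sigma = np.log(cfg.cap_diameter_gsd)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        ok = draw[(draw > cfg.cap_diameter_min_um) & (draw < cfg.cap_diameter_max_um)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _correlated_capillary_diameters(rng, cfg: SynthConfig, n_nodes, edge_nodes):
    """Spatially correlated lognormal diameters from a smoothed node field.

    A standard-normal value per node is averaged over graph neighbours for
    ``diameter_smoothing_sweeps`` sweeps, re-standardized, and evaluated at
    each vessel as the mean of its endpoint values, so adjacent segments —
    in particular the two daughters of a bifurcation — have similar
    calibres, as in real capillary beds.  The marginal law stays
    lognormal(median, gsd), truncated by clipping.
    """
    z = rng.standard_normal(n_nodes)
    adj = [[] for _ in range(n_nodes)]
    for a, b in edge_nodes:
        adj[a].append(b)
        adj[b].append(a)
    for _ in range(cfg.diameter_smoothing_sweeps):
        z = np.array(
            [(z[i] + sum(z[k] for k in adj[i])) / (1 + len(adj[i])) for i in range(n_nodes)]
        )
    if z.std() > 0:
        z = (z - z.mean()) / z.std()
    zv = np.array([0.5 * (z[a] + z[b]) for a, b in edge_nodes])
    if zv.std() > 0:
        zv = (zv - zv.mean()) / zv.std()
    d = cfg.cap_diameter_median_um * np.exp(np.log(cfg.cap_diameter_gsd) * zv)
    lo = cfg.cap_diameter_min_um + 0.1 * (cfg.cap_diameter_median_um - cfg.cap_diameter_min_um)
    return np.clip(d, lo, cfg.cap_diameter_max_um)


def _thin_to_mean_degree(n_nodes, edges, target_mean_degree, rng):
    """Randomly remove non-bridge edges, never dropping a node below degree 2."""
    adj = {i: set() for i in range(n_nodes)}
    edge_set = set()
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
        edge_set.add((min(a, b), max(a, b)))
    target_edges = int(round(target_mean_degree * n_nodes / 2.0))

    def connected_without(a, b):
        # BFS from a to b with edge (a, b) masked out
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if u == a and w == b:
                    continue
                if w == b:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    candidates = list(edge_set)
    rng.shuffle(candidates)
    for a, b in candidates:
        if len(edge_set) <= target_edges:
            break
        if len(adj[a]) <= 2 or len(adj[b]) <= 2:
            continue
        if not connected_without(a, b):
            continue
        adj[a].discard(b)
        adj[b].discard(a)
        edge_set.discard((min(a, b), max(a, b)))
    return sorted(edge_set)


def _trunk_columns(cfg: SynthConfig):
    """Deterministic interior (x, y) grid columns for DA and AV trunks.

    DAs and AVs alternate over quarter-point positions so that capillary
    paths between them span a few mesh segments, as in the cortex.
    """
    qx = [cfg.nx // 4 + 1, (3 * cfg.nx) // 4 - 1, cfg.nx // 2]
    qy = [cfg.ny // 4 + 1, (3 * cfg.ny) // 4 - 1, cfg.ny // 2]
    if len(set(qx)) == 1 or len(set(qy)) == 1:  # small lattices collapse quarters
        qx = [1, cfg.nx - 2, cfg.nx // 2]
        qy = [1, cfg.ny - 2, cfg.ny // 2]
    spots = [
        (qx[0], qy[0]),
        (qx[1], qy[1]),
        (qx[0], qy[1]),
        (qx[1], qy[0]),
        (qx[2], qy[2]),
        (qx[2], qy[0]),
        (qx[0], qy[2]),
        (qx[2], qy[1]),
        (qx[1], qy[2]),
    ]
    uniq = []
    for s in spots:
        if s not in uniq:
            uniq.append(s)
    if cfg.n_da + cfg.n_av > len(uniq):
        raise ValueError("too many penetrating trunks for this lattice size")
    da = [uniq[2 * k] if 2 * k < len(uniq) else uniq[k] for k in range(cfg.n_da)]
    remaining = [s for s in uniq if s not in da]
    av = remaining[: cfg.n_av]
    return da, av


def generate_lattice_mvn(config: SynthConfig) -> VascularGraph:
    """Build, validate and return the synthetic network for this config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.nx, cfg.ny, cfg.nz
    h = cfg.spacing_um

    def grid_index(i, j, k):
        return (k * ny + j) * nx + i

    n_cap = nx * ny * nz
    base = np.empty((n_cap, 3))
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                base[grid_index(i, j, k)] = (i * h, j * h, (k + 1) * h)
    pos = base + rng.uniform(-cfg.jitter * h, cfg.jitter * h, size=base.shape)

    lattice_edges = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                a = grid_index(i, j, k)
                if i + 1 < nx:
                    lattice_edges.append((a, grid_index(i + 1, j, k)))
                if j + 1 < ny:
                    lattice_edges.append((a, grid_index(i, j + 1, k)))
                if k + 1 < nz:
                    lattice_edges.append((a, grid_index(i, j, k + 1)))
    mesh_edges = _thin_to_mean_degree(n_cap, lattice_edges, cfg.mean_degree, rng)

    da_cols, av_cols = _trunk_columns(cfg)

    node_pos = [pos]
    extra_pos = []
    is_boundary = [False] * n_cap
    boundary_p = [np.nan] * n_cap
    next_node = n_cap

    vessels = []  # (node_a, node_b, diameter, type)

    def add_trunk(col, vtype, p_boundary):
        nonlocal next_node
        cx, cy = col
        # trunk offset from its column so offshoots keep a workable length
        tx = cx * h + 0.6 * h
        ty = cy * h
        ids = []
        top = next_node
        extra_pos.append((tx, ty, 0.0))
        is_boundary.append(True)
        boundary_p.append(p_boundary)
        next_node += 1
        prev = top
        for k in range(nz):
            tid = next_node
            extra_pos.append((tx, ty, (k + 1) * h))
            is_boundary.append(False)
            boundary_p.append(np.nan)
            next_node += 1
            vessels.append((prev, tid, cfg.trunk_diameter_um, vtype))
            # per-level offshoot into the capillary mesh (capillary calibre,
            # sampled with the mesh so its resistance throttles the level)
            cap_node = grid_index(cx, cy, k)
            vessels.append((tid, cap_node, None, "capillary"))
            prev = tid
            ids.append(tid)
        return ids

    for col in da_cols:
        add_trunk(col, "descending_arteriole", cfg.p_inlet_mmhg)
    for col in av_cols:
        add_trunk(col, "ascending_venule", cfg.p_outlet_mmhg)

    for a, b in mesh_edges:
        vessels.append((a, b, None, "capillary"))

    all_pos = np.vstack([pos, np.array(extra_pos)]) if extra_pos else pos
    n_nodes = next_node

    need = [k for k, v in enumerate(vessels) if v[2] is None]
    if cfg.diameter_smoothing_sweeps > 0:
        cap_d = _correlated_capillary_diameters(
            rng, cfg, n_nodes, [(vessels[k][0], vessels[k][1]) for k in need]
        )
    else:
        cap_d = _sample_capillary_diameters(rng, len(need), cfg)
    cap_d = iter(cap_d)
    node_from = np.array([v[0] for v in vessels], dtype=np.int64)
    node_to = np.array([v[1] for v in vessels], dtype=np.int64)
    diam = np.array([v[2] if v[2] is not None else next(cap_d) for v in vessels])
    vtype = np.array([v[3] for v in vessels], dtype=object)
    length = np.linalg.norm(all_pos[node_to] - all_pos[node_from], axis=1)

    g = VascularGraph(
        node_id=np.arange(n_nodes),
        pos_um=all_pos,
        is_boundary=np.array(is_boundary),
        boundary_pressure_mmhg=np.array(boundary_p, dtype=float),
        vessel_id=np.arange(len(vessels)),
        node_from=node_from,
        node_to=node_to,
        length_um=length,
        diameter_um=diam,
        vtype=vtype,
    )
    return g.validate()


def generate_toy_bifurcation(
    d_mother_um,
    d_d1_um,
    d_d2_um,
    length_um,
    p_in_mmhg,
    p_out1_mmhg,
    p_out2_mmhg,
    vtype="capillary",
) -> VascularGraph:
    """Four-node Y graph: one mother vessel splitting into two daughters.

    The workhorse fixture for phase-separation and balancing unit tests.
    All three vessels share the same length; boundary pressures are imposed
    at the inlet and the two outlets.
    """
    L = float(length_um)
    if L <= 0:
        raise ValueError("length must be positive")
    # daughters run diagonally with endpoint distance exactly L
    pos = np.array(
        [
            [0.0, 0.0, L],
            [L, 0.0, L],
            [L + 0.8 * L, 0.6 * L, L],
            [L + 0.8 * L, -0.6 * L, L],
        ]
    )
    g = VascularGraph(
        node_id=np.arange(4),
        pos_um=pos,
        is_boundary=np.array([True, False, True, True]),
        boundary_pressure_mmhg=np.array(
            [p_in_mmhg, np.nan, p_out1_mmhg, p_out2_mmhg], dtype=float
        ),
        vessel_id=np.arange(3),
        node_from=np.array([0, 1, 1]),
        node_to=np.array([1, 2, 3]),
        length_um=np.array([L, L, L]),
        diameter_um=np.array([d_mother_um, d_d1_um, d_d2_um], dtype=float),
        vtype=np.array([vtype, vtype, vtype], dtype=object),
    )
    return g.validate()
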