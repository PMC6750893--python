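"""Vascular graph data model, CSV I/O, validation and flow-directed traversal.

A microvascular network is a graph whose nodes are bifurcations (plus the
in-/outflow endpoints) and whose edges are vessel segments.  Geometry is
stored in micrometres, pressures in mmHg — the conventions of the file
format; hemodynamic computations convert to SI at their call boundary.

Vessel orientation (``node_from`` -> ``node_to``) is a storage convention
only: the sign of the flow relative to that orientation defines the actual
flow direction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VESSEL_TYPES = (
    "pial_arteriole",
    "descending_arteriole",
    "capillary",
    "ascending_venule",
    "pial_venule",
)

NODE_COLUMNS = ["node_id", "x_um", "y_um", "z_um", "is_boundary", "boundary_pressure_mmHg"]
VESSEL_COLUMNS = ["vessel_id", "node_from", "node_to", "length_um", "diameter_um", "type"]

#: a vessel may be up to this fraction shorter than the straight-line
#: distance between its endpoints before validation rejects it
TORTUOSITY_TOLERANCE = 0.01


class GraphFormatError(ValueError):
    """A graph file does not follow the documented CSV dialect."""


class GraphIntegrityError(ValueError):
    """Graph-level referential or topological invariant violated."""


@dataclass
class VascularGraph:
    """Array-backed vascular network.

    Nodes and vessels are stored as parallel numpy arrays; ``node_from_idx``
    and ``node_to_idx`` are positional indices into the node arrays so that
    solvers never need an id lookup.
    """

    node_id: np.ndarray            # (n,) int
    pos_um: np.ndarray             # (n, 3) float
    is_boundary: np.ndarray        # (n,) bool
    boundary_pressure_mmhg: np.ndarray  # (n,) float, NaN for interior nodes

    vessel_id: np.ndarray          # (m,) int
    node_from: np.ndarray          # (m,) int, node ids
    node_to: np.ndarray            # (m,) int, node ids
    length_um: np.ndarray          # (m,) float
    diameter_um: np.ndarray        # (m,) float
    vtype: np.ndarray              # (m,) str

    node_from_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    node_to_idx: np.ndarray = field(default=None)    # type: ignore[assignment]

    def __post_init__(self):
        self.node_id = np.asarray(self.node_id, dtype=np.int64)
        self.pos_um = np.asarray(self.pos_um, dtype=float)
        self.is_boundary = np.asarray(self.is_boundary, dtype=bool)
        self.boundary_pressure_mmhg = np.asarray(self.boundary_pressure_mmhg, dtype=float)
        self.vessel_id = np.asarray(self.vessel_id, dtype=np.int64)
        self.node_from = np.asarray(self.node_from, dtype=np.int64)
        self.node_to = np.asarray(self.node_to, dtype=np.int64)
        self.length_um = np.asarray(self.length_um, dtype=float)
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        self.vtype = np.asarray(self.vtype, dtype=object)
        if self.node_from_idx is None:
            lookup = {nid: i for i, nid in enumerate(self.node_id)}
            missing = [
                (v, n)
                for v, n in zip(
                    np.concatenate([self.vessel_id, self.vessel_id]),
                    np.concatenate([self.node_from, self.node_to]),
                )
                if n not in lookup
            ]
            if missing:
                v, n = missing[0]
                raise GraphIntegrityError(
                    f"vessel {v} references node id {n} absent from the nodes table"
                )
            self.node_from_idx = np.array([lookup[n] for n in self.node_from], dtype=np.int64)
            self.node_to_idx = np.array([lookup[n] for n in self.node_to], dtype=np.int64)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_id)

    @property
    def n_vessels(self) -> int:
        return len(self.vessel_id)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.node_from_idx, 1)
        np.add.at(deg, self.node_to_idx, 1)
        return deg

    def incident_vessels(self) -> list[list[int]]:
        """Positional vessel indices incident to each node."""
        inc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for j in range(self.n_vessels):
            inc[self.node_from_idx[j]].append(j)
            inc[self.node_to_idx[j]].append(j)
        return inc

    def vessel_index(self, vessel_id: int) -> int:
        pos = np.flatnonzero(self.vessel_id == vessel_id)
        if len(pos) == 0:
            raise KeyError(f"no vessel with id {vessel_id}")
        return int(pos[0])

    def node_index(self, node_id: int) -> int:
        pos = np.flatnonzero(self.node_id == node_id)
        if len(pos) == 0:
            raise KeyError(f"no node with id {node_id}")
        return int(pos[0])

    def cross_section_um2(self) -> np.ndarray:
        return np.pi / 4.0 * self.diameter_um**2

    def euclidean_lengths_um(self) -> np.ndarray:
        d = self.pos_um[self.node_to_idx] - self.pos_um[self.node_from_idx]
        return np.linalg.norm(d, axis=1)

    # -- validation --------------------------------------------------------

    def validate(self) -> "VascularGraph":
        """Check every structural invariant; raise with the offending row."""
        if len(np.unique(self.node_id)) != self.n_nodes:
            dup = pd.Series(self.node_id).value_counts()
            raise GraphIntegrityError(f"duplicate node id {dup.index[0]}")
        if len(np.unique(self.vessel_id)) != self.n_vessels:
            dup = pd.Series(self.vessel_id).value_counts()
            raise GraphIntegrityError(f"duplicate vessel id {dup.index[0]}")
        if not np.all(np.isfinite(self.pos_um)):
            bad = self.node_id[~np.all(np.isfinite(self.pos_um), axis=1)][0]
            raise ValueError(f"node {bad} has a non-finite position")
        bad = np.flatnonzero(self.length_um <= 0)
        if len(bad):
            raise ValueError(f"vessel {self.vessel_id[bad[0]]} has non-positive length")
        bad = np.flatnonzero(self.diameter_um <= 0)
        if len(bad):
            raise ValueError(f"vessel {self.vessel_id[bad[0]]} has non-positive diameter")
        bad = np.flatnonzero(self.node_from_idx == self.node_to_idx)
        if len(bad):
            raise GraphIntegrityError(f"vessel {self.vessel_id[bad[0]]} is a self-loop")
        unknown = ~np.isin(self.vtype.astype(str), VESSEL_TYPES)
        if unknown.any():
            j = np.flatnonzero(unknown)[0]
            raise GraphFormatError(
                f"vessel {self.vessel_id[j]} has unknown type {self.vtype[j]!r}"
            )
        # tortuosity: a vessel cannot be shorter than the straight line
        chord = self.euclidean_lengths_um()
        short = np.flatnonzero(self.length_um < chord * (1.0 - TORTUOSITY_TOLERANCE))
        if len(short):
            j = short[0]
            raise ValueError(
                f"vessel {self.vessel_id[j]}: length {self.length_um[j]:.3g} um is below the "
                f"endpoint distance {chord[j]:.3g} um"
            )
        deg = self.degrees()
        b = np.flatnonzero(self.is_boundary & (deg != 1))
        if len(b):
            raise GraphIntegrityError(
                f"boundary node {self.node_id[b[0]]} has degree {deg[b[0]]} (expected 1)"
            )
        i = np.flatnonzero(~self.is_boundary & (deg < 2))
        if len(i):
            raise GraphIntegrityError(
                f"interior node {self.node_id[i[0]]} has degree {deg[i[0]]} (< 2)"
            )
        interior_bc = np.flatnonzero(~self.is_boundary & np.isfinite(self.boundary_pressure_mmhg))
        if len(interior_bc):
            raise GraphFormatError(
                f"interior node {self.node_id[interior_bc[0]]} carries a boundary pressure"
            )
        missing_bc = np.flatnonzero(self.is_boundary & ~np.isfinite(self.boundary_pressure_mmhg))
        if len(missing_bc):
            raise GraphFormatError(
                f"boundary node {self.node_id[missing_bc[0]]} has no boundary pressure"
            )
        if not self._is_connected():
            raise GraphIntegrityError("graph is not connected")
        return self

    def _is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        a = coo_matrix(
            (np.ones(self.n_vessels), (self.node_from_idx, self.node_to_idx)),
            shape=(self.n_nodes, self.n_nodes),
        )
        n_comp, _ = connected_components(a, directed=False)
        return n_comp == 1

    # -- dataframe / file round trip ---------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            {
                "node_id": self.node_id,
                "x_um": self.pos_um[:, 0],
                "y_um": self.pos_um[:, 1],
                "z_um": self.pos_um[:, 2],
                "is_boundary": self.is_boundary.astype(int),
                "boundary_pressure_mmHg": self.boundary_pressure_mmhg,
            }
        )
        vessels = pd.DataFrame(
            {
                "vessel_id": self.vessel_id,
                "node_from": self.node_from,
                "node_to": self.node_to,
                "length_um": self.length_um,
                "diameter_um": self.diameter_um,
                "type": self.vtype.astype(str),
            }
        )
        return nodes, vessels

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, vessels: pd.DataFrame) -> "VascularGraph":
        for col in NODE_COLUMNS:
            if col not in nodes.columns:
                raise GraphFormatError(f"nodes table is missing column {col!r}")
        for col in VESSEL_COLUMNS:
            if col not in vessels.columns:
                raise GraphFormatError(f"vessels table is missing column {col!r}")
        g = cls(
            node_id=nodes["node_id"].to_numpy(),
            pos_um=nodes[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            is_boundary=nodes["is_boundary"].to_numpy().astype(bool),
            boundary_pressure_mmhg=pd.to_numeric(
                nodes["boundary_pressure_mmHg"], errors="coerce"
            ).to_numpy(dtype=float),
            vessel_id=vessels["vessel_id"].to_numpy(),
            node_from=vessels["node_from"].to_numpy(),
            node_to=vessels["node_to"].to_numpy(),
            length_um=vessels["length_um"].to_numpy(dtype=float),
            diameter_um=vessels["diameter_um"].to_numpy(dtype=float),
            vtype=vessels["type"].to_numpy(dtype=object),
        )
        return g.validate()

    def equals(self, other: "VascularGraph") -> bool:
        return (
            np.array_equal(self.node_id, other.node_id)
            and np.allclose(self.pos_um, other.pos_um, rtol=0, atol=1e-9)
            and np.array_equal(self.is_boundary, other.is_boundary)
            and np.allclose(
                self.boundary_pressure_mmhg, other.boundary_pressure_mmhg, equal_nan=True
            )
            and np.array_equal(self.vessel_id, other.vessel_id)
            and np.array_equal(self.node_from, other.node_from)
            and np.array_equal(self.node_to, other.node_to)
            and np.allclose(self.length_um, other.length_um, rtol=0, atol=1e-9)
            and np.allclose(self.diameter_um, other.diameter_um, rtol=0, atol=1e-9)
            and np.array_equal(self.vtype.astype(str), other.vtype.astype(str))
        )


def read_graph(nodes_path, vessels_path) -> VascularGraph:
    """Read and validate a graph from the documented nodes/vessels CSV pair."""
    nodes = pd.read_csv(nodes_path)
    vessels = pd.read_csv(vessels_path)
    return VascularGraph.from_frames(nodes, vessels)


def write_graph(graph: VascularGraph, nodes_path, vessels_path) -> None:
    """Write the nodes/vessels CSV pair (UTF-8, '.' decimal, header row)."""
    nodes, vessels = graph.to_frames()
    # a fixed round-trip float format keeps files byte-identical across runs
    for path, frame in ((nodes_path, nodes), (vessels_path, vessels)):
        buf = io.StringIO()
        frame.to_csv(buf, index=False, float_format="%.17g")
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(buf.getvalue())


def generations_up_downstream(graph, field, site, n):
    """Vessel sets at signed generations around a divergent bifurcation.

    Generation 0 is the site itself (mother and both daughters) and is
    excluded.  Upstream generation -1 holds the vessels delivering flow into
    the mother's tail node; downstream generation +1 the first vessels
    downstream of the daughters; and so on outward.  A vessel reachable at
    several depths is kept at the smallest ``|generation|``; ties between
    upstream and downstream assign upstream.  Zero-flow vessels terminate
    the walk and are excluded.

    Parameters
    ----------
    field : object or array
        Either a :class:`~capflow.runner.TimeAveragedField` (its
        ``direction`` attribute is used) or a per-vessel array of flow signs
        relative to storage orientation (+1, -1, or 0).
    site : int
        Node id of a degree-3 bifurcation.

    Returns
    -------
    dict mapping signed generation (-n..-1, +1..+n) to sets of vessel ids.
    """
    direction = np.asarray(getattr(field, "direction", field))
    s = graph.node_index(site)
    inc = graph.incident_vessels()
    if len(inc[s]) != 3:
        raise ValueError(f"site {site} has degree {len(inc[s])}, expected 3")

    def head(j):  # node index the flow enters
        return graph.node_to_idx[j] if direction[j] > 0 else graph.node_from_idx[j]

    def tail(j):  # node index the flow leaves
        return graph.node_from_idx[j] if direction[j] > 0 else graph.node_to_idx[j]

    gen0 = set(inc[s])
    mothers = [j for j in inc[s] if direction[j] != 0 and head(j) == s]
    daughters = [j for j in inc[s] if direction[j] != 0 and tail(j) == s]

    assigned: dict[int, int] = {}
    out: dict[int, set[int]] = {g: set() for g in range(-n, 0)}
    out.update({g: set() for g in range(1, n + 1)})

    up_frontier = {tail(j) for j in mothers}
    down_frontier = {head(j) for j in daughters}
    for g in range(1, n + 1):
        new_up: set[int] = set()
        for node in up_frontier:
            for j in inc[node]:
                if j in gen0 or j in assigned or direction[j] == 0:
                    continue
                if head(j) == node:  # delivers flow into the frontier node
                    assigned[j] = -g
                    out[-g].add(int(graph.vessel_id[j]))
                    new_up.add(tail(j))
        new_down: set[int] = set()
        for node in down_frontier:
            for j in inc[node]:
                if j in gen0 or j in assigned or direction[j] == 0:
                    continue
                if tail(j) == node:  # carries flow away from the frontier node
                    assigned[j] = g
                    out[g].add(int(graph.vessel_id[j]))
                    new_down.add(head(j))
        up_frontier, down_frontier = new_up, new_down
    return out
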