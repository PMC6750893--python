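"""Discrete tracking of individual red blood cells on the vascular graph.

Each RBC is a point particle with a finite volume V_RBC.  Inside a vessel
it occupies a length l_RBC = V_RBC / A (A the cross-section), moves at the
bulk velocity times the Fahraeus factor H_d/H_t, and may never come closer
than l_RBC to the cell ahead of it (traffic jams).  At divergent
bifurcations the cells and the plasma split in different proportions
(phase separation): for mother diameters >= 10 um the empirical logit law
of Pries et al. governs the red-cell flux fraction, while in capillaries
(< 10 um) each cell follows the daughter exerting the larger pressure
force (pressure gradient times cross-section) — the bifurcation rule.

Model variants:

``with_rbcs``
    full model — Fahraeus-Lindqvist resistance, Fahraeus velocity factor
    and phase separation;
``passive_particles``
    tracked cells neither raise resistance nor phase-separate and move at
    the bulk velocity; they split like the bulk flow except for jams;
``no_phase_separation``
    cells keep their resistance and velocity effects but split like the
    bulk flow.

Implementation note: cell positions are stored per vessel in the *travel*
coordinate (0 at the flow entrance, L at the exit), kept sorted ascending,
minus a per-vessel offset that absorbs the uniform per-step motion — so a
time step shifts whole vessels in O(1) and only node crossings, jams and
insertions touch individual cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import hemodynamics as hd

#: RBC volume in um^3 (mouse); configurable per simulation
V_RBC_UM3 = 49.0


class ModelVariant(str, Enum):
    WITH_RBCS = "with_rbcs"
    PASSIVE_PARTICLES = "passive_particles"
    NO_PHASE_SEPARATION = "no_phase_separation"


@dataclass(frozen=True)
class PhaseSeparationParams:
    """Coefficients of the empirical red-cell flux split (logit law).

    With mother diameter Df and daughter diameters D1, D2 (um):
    A = a_coeff ln(D1/D2)/Df, B = 1 + b_coeff (1 - H_d)/Df,
    X0 = x0_coeff/Df.  Below ``d_star`` the bifurcation rule replaces the
    law entirely.
    """

    a_coeff: float = -6.96
    b_coeff: float = 6.98
    x0_coeff: float = 0.4
    d_star_um: float = 10.0


DEFAULT_PS_PARAMS = PhaseSeparationParams()


def rbc_velocity(v_bulk, h_t, h_d, variant=ModelVariant.WITH_RBCS):
    """Cell velocity from bulk velocity and the Fahraeus factor H_d/H_t.

    Cells travel in the faster core of the velocity profile, so on average
    v_RBC = v_bulk * H_d/H_t >= v_bulk.  Passive particles move with the
    bulk flow.
    """
    v_bulk = np.asarray(v_bulk, dtype=float)
    if ModelVariant(variant) == ModelVariant.PASSIVE_PARTICLES:
        return v_bulk
    h_t = np.asarray(h_t, dtype=float)
    h_d = np.asarray(h_d, dtype=float)
    factor = np.where(h_t > 0, np.maximum(h_d / np.where(h_t > 0, h_t, 1.0), 1.0), 1.0)
    return v_bulk * factor


def pries_split_fraction(fqb, d_mother_um, d_d1_um, d_d2_um, h_d,
                         params: PhaseSeparationParams = DEFAULT_PS_PARAMS):
    """Fractional RBC flux into daughter 1 given its fractional bulk flow.

    Pure plasma skimming below X0 (no cells enter) and full capture above
    1 - X0; a logit-linear law in between.  Swapping the daughters maps
    FQE to 1 - FQE.
    """
    fqb = float(fqb)
    if not 0.0 <= fqb <= 1.0:
        raise ValueError("fractional bulk flow must lie in [0, 1]")
    df = float(d_mother_um)
    x0 = params.x0_coeff / df
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    a = params.a_coeff * math.log(d_d1_um / d_d2_um) / df
    b = 1.0 + params.b_coeff * (1.0 - h_d) / df
    x = (fqb - x0) / (1.0 - 2.0 * x0)
    logit = a + b * math.log(x / (1.0 - x))
    return 1.0 / (1.0 + math.exp(-logit))


def bifurcation_rule_choice(forces, rng, blocked=None):
    """Index of the daughter with the larger pressure force.

    ``forces`` are (dp/L) * A per candidate daughter; exact ties are broken
    by a fair coin from ``rng``.  A blocked daughter (entrance at packing
    limit) yields to the other; returns ``None`` if every candidate is
    blocked (the cell waits).
    """
    forces = list(forces)
    if blocked is None:
        blocked = [False] * len(forces)
    order = sorted(range(len(forces)), key=lambda i: -forces[i])
    # fair coin on exact ties of the two best candidates
    if len(order) >= 2 and forces[order[0]] == forces[order[1]]:
        if rng.random() < 0.5:
            order[0], order[1] = order[1], order[0]
    for i in order:
        if not blocked[i]:
            return i
    return None


class VesselTables:
    """Per-vessel lookup tables from RBC count to hemodynamic quantities.

    The cell count n in a vessel determines its tube hematocrit
    H_t = n V_RBC / (A L); inverting the Fahraeus relation gives the
    discharge hematocrit H_d feeding the viscosity law and the velocity
    factor.  Since n is a small integer, every quantity is precomputed once
    per vessel so a time step reduces to a table lookup.
    """

    def __init__(self, graph, variant=ModelVariant.WITH_RBCS,
                 params: hd.ResistanceParams = hd.DEFAULT_PARAMS,
                 v_rbc_um3: float = V_RBC_UM3):
        self.graph = graph
        self.variant = ModelVariant(variant)
        self.v_rbc_um3 = float(v_rbc_um3)
        area_um2 = graph.cross_section_um2()
        self.area_um2 = area_um2
        self.l_rbc_um = self.v_rbc_um3 / area_um2
        length_um = graph.length_um
        self.n_max = np.floor(length_um / self.l_rbc_um).astype(np.int64) + 1

        r_plasma = hd.plasma_resistance(length_um * 1e-6, graph.diameter_um * 1e-6,
                                        params.mu_plasma)
        self.r_plasma = r_plasma

        offsets = np.concatenate([[0], np.cumsum(self.n_max + 1)])
        self.offsets = offsets[:-1]
        total = int(offsets[-1])
        ht = np.empty(total)
        hdis = np.empty(total)
        eta = np.empty(total)
        vfac = np.empty(total)
        for j in range(graph.n_vessels):
            n = np.arange(self.n_max[j] + 1)
            ht_j = np.clip(n * self.v_rbc_um3 / (area_um2[j] * length_um[j]), 0.0, 1.0)
            hd_j = np.asarray(hd.discharge_from_tube(graph.diameter_um[j], ht_j))
            # the viscosity law is undefined at H_d = 1; cap just below
            hd_eta = np.minimum(hd_j, 0.99)
            eta_j = hd.relative_apparent_viscosity(graph.diameter_um[j], hd_eta, params)
            with np.errstate(divide="ignore", invalid="ignore"):
                vfac_j = np.where(
                    ht_j > 0, np.maximum(hd_j / np.where(ht_j > 0, ht_j, 1.0), 1.0), 1.0
                )
            sl = slice(self.offsets[j], self.offsets[j] + self.n_max[j] + 1)
            ht[sl] = ht_j
            hdis[sl] = hd_j
            eta[sl] = eta_j
            vfac[sl] = vfac_j
        self._ht = ht
        self._hd = hdis
        if self.variant == ModelVariant.PASSIVE_PARTICLES:
            self._reff = np.repeat(r_plasma, self.n_max + 1)
            self._vfac = np.ones(total)
        else:
            self._reff = np.repeat(r_plasma, self.n_max + 1) * eta
            self._vfac = vfac

    def _idx(self, counts):
        return self.offsets + np.minimum(counts, self.n_max)

    def tube_hematocrit(self, counts):
        return self._ht[self._idx(counts)]

    def discharge_hematocrit(self, counts):
        return self._hd[self._idx(counts)]

    def resistance(self, counts):
        return self._reff[self._idx(counts)]

    def velocity_factor(self, counts):
        return self._vfac[self._idx(counts)]


class RBCState:
    """Positions of all tracked cells, grouped per vessel.

    Externally, positions are arc lengths ``s`` in um along the storage
    orientation.  Internally each vessel keeps travel coordinates (0 =
    flow entrance) minus a shared offset; see the module docstring.  The
    ledger counters ``n_injected`` and ``n_ejected`` allow exact
    bookkeeping over any horizon.
    """

    def __init__(self, graph, v_rbc_um3: float = V_RBC_UM3):
        self.graph = graph
        self.v_rbc_um3 = float(v_rbc_um3)
        m = graph.n_vessels
        self._t: list[list[float]] = [[] for _ in range(m)]   # stored travel coords
        self._ids: list[list[int]] = [[] for _ in range(m)]
        self._off = np.zeros(m)
        self._dirn = np.ones(m, dtype=np.int8)  # +1: travel runs node_from -> node_to
        self._counts = np.zeros(m, dtype=np.int64)
        self._next_id = 0
        self.n_injected = 0
        self.n_ejected = 0
        self._area = graph.cross_section_um2()
        self.l_rbc_um = self.v_rbc_um3 / self._area

    # -- construction ------------------------------------------------------

    @classmethod
    def from_uniform_hematocrit(cls, graph, h_d=0.3, v_rbc_um3: float = V_RBC_UM3,
                                vessel_mask=None):
        """Seed every (masked) vessel with evenly spaced cells at the tube
        hematocrit corresponding to discharge hematocrit ``h_d``."""
        state = cls(graph, v_rbc_um3)
        ht = hd.tube_from_discharge(graph.diameter_um, h_d)
        for j in range(graph.n_vessels):
            if vessel_mask is not None and not vessel_mask[j]:
                continue
            L = graph.length_um[j]
            n = int(round(ht[j] * state._area[j] * L / v_rbc_um3))
            n = min(n, int(L / state.l_rbc_um[j]))
            if n <= 0:
                continue
            pos = (np.arange(n) + 0.5) * (L / n)
            state._t[j] = list(pos)
            state._ids[j] = [state._take_id() for _ in range(n)]
            state._counts[j] = n
        return state

    def _take_id(self):
        i = self._next_id
        self._next_id += 1
        return i

    # -- coordinate handling -----------------------------------------------

    def _rebase(self, j, new_dirn):
        """Re-express vessel j's travel coordinates for a reversed flow."""
        if self._dirn[j] == new_dirn:
            return
        L = self.graph.length_um[j]
        off = self._off[j]
        self._t[j] = [L - (x + off) for x in reversed(self._t[j])]
        self._ids[j] = list(reversed(self._ids[j]))
        self._off[j] = 0.0
        self._dirn[j] = new_dirn

    def positions_s_um(self, j):
        """Arc-length positions (storage orientation) in vessel j, ascending."""
        off = self._off[j]
        t = [x + off for x in self._t[j]]
        if self._dirn[j] > 0:
            return t
        L = self.graph.length_um[j]
        return [L - x for x in reversed(t)]

    def items_s(self, j):
        """(s_um, rbc_id) pairs in vessel j, ascending by arc length."""
        ids = self._ids[j] if self._dirn[j] > 0 else list(reversed(self._ids[j]))
        return list(zip(self.positions_s_um(j), ids))

    # -- inspection --------------------------------------------------------

    @property
    def n_rbcs(self) -> int:
        return int(self._counts.sum())

    def counts(self) -> np.ndarray:
        return self._counts.copy()

    def tube_hematocrit(self) -> np.ndarray:
        return np.clip(
            self._counts * self.v_rbc_um3 / (self._area * self.graph.length_um), 0.0, 1.0
        )

    def min_spacing_ratio(self) -> float:
        """Smallest gap between consecutive cells in units of l_RBC (inf if
        no vessel holds two cells).  >= 1 - tol when the jam contract holds."""
        worst = np.inf
        for j, t in enumerate(self._t):
            if len(t) >= 2:
                gaps = np.diff(t)
                worst = min(worst, float(gaps.min() / self.l_rbc_um[j]))
        return worst

    def to_frame(self, t=0.0):
        import pandas as pd

        rows = []
        for j in range(self.graph.n_vessels):
            vid = self.graph.vessel_id[j]
            ids = self._ids[j] if self._dirn[j] > 0 else list(reversed(self._ids[j]))
            for s, i in zip(self.positions_s_um(j), ids):
                rows.append((t, i, vid, s))
        return pd.DataFrame(rows, columns=["t", "rbc_id", "vessel_id", "s_um"])

    def copy(self) -> "RBCState":
        new = RBCState(self.graph, self.v_rbc_um3)
        new._t = [list(t) for t in self._t]
        new._ids = [list(i) for i in self._ids]
        new._off = self._off.copy()
        new._dirn = self._dirn.copy()
        new._counts = self._counts.copy()
        new._next_id = self._next_id
        new.n_injected = self.n_injected
        new.n_ejected = self.n_ejected
        return new


class RBCTransport:
    """Advance and inject cells on a fixed graph for one model variant."""

    def __init__(self, graph, variant=ModelVariant.WITH_RBCS,
                 ps_params: PhaseSeparationParams = DEFAULT_PS_PARAMS,
                 v_rbc_um3: float = V_RBC_UM3):
        self.graph = graph
        self.variant = ModelVariant(variant)
        self.ps = ps_params
        self.v_rbc_um3 = float(v_rbc_um3)
        self.area_um2 = graph.cross_section_um2()
        self.inv_area_m2 = 1.0 / (self.area_um2 * 1e-12)
        self.l_rbc_um = self.v_rbc_um3 / self.area_um2
        self.incident = graph.incident_vessels()
        # vessels touching a boundary node (the only injection/ejection sites)
        self.boundary_vessels = [
            j for j in range(graph.n_vessels)
            if graph.is_boundary[graph.node_from_idx[j]]
            or graph.is_boundary[graph.node_to_idx[j]]
        ]
        self._inject_acc: dict[int, float] = {}
        #: cells removed at each boundary node (node index -> count)
        self.ejections_by_node: dict[int, int] = {}
        #: cells routed into each vessel at a node crossing (vessel -> count)
        self.routings_by_vessel: dict[int, int] = {}

    # -- helpers -----------------------------------------------------------

    def _head_node(self, j, q):
        """Node index the flow in vessel j is entering."""
        return self.graph.node_to_idx[j] if q[j] >= 0 else self.graph.node_from_idx[j]

    def _tail_node(self, j, q):
        return self.graph.node_from_idx[j] if q[j] >= 0 else self.graph.node_to_idx[j]

    def _entry_clearance(self, state, j):
        """Travel-coordinate room at the entrance of vessel j (< 0: blocked).

        Assumes vessel j's stored direction matches the current flow (the
        advance loop rebases every moving vessel first).
        """
        t = state._t[j]
        if not t:
            return self.graph.length_um[j]
        return (t[0] + state._off[j]) - self.l_rbc_um[j]

    def _insert(self, state, j, travel_pos, rbc_id, q):
        sgn = 1 if q[j] >= 0 else -1
        if state._counts[j] == 0:
            state._off[j] = 0.0
            state._dirn[j] = sgn
        else:
            state._rebase(j, sgn)
        state._t[j].insert(0, travel_pos - state._off[j])
        state._ids[j].insert(0, rbc_id)
        state._counts[j] += 1

    def _cascade_clamp(self, state, j):
        """Re-impose the minimum spacing from the waiting leader inward."""
        t = state._t[j]
        off = state._off[j]
        l_rbc = self.l_rbc_um[j]
        cap = self.graph.length_um[j] - off
        for i in range(len(t) - 1, -1, -1):
            if t[i] > cap:
                t[i] = cap
            cap = t[i] - l_rbc

    def _choose_daughter(self, state, flow, mother_j, node, out_vessels, h_d_mother, rng):
        """Variant-dependent routing decision; returns target vessel or None."""
        g = self.graph
        q = flow.q_m3s
        p = flow.pressures_pa
        blocked = [self._entry_clearance(state, k) < 0.0 for k in out_vessels]
        if len(out_vessels) == 1:
            return None if blocked[0] else out_vessels[0]

        qmag = [abs(q[k]) for k in out_vessels]
        if self.variant != ModelVariant.WITH_RBCS:
            # bulk-flow proportional split (passive / no-phase-separation)
            total = sum(qmag)
            r = rng.random() * total
            acc = 0.0
            pick = len(out_vessels) - 1
            for i, qm in enumerate(qmag):
                acc += qm
                if r < acc:
                    pick = i
                    break
            order = [pick] + [i for i in range(len(out_vessels)) if i != pick]
            for i in order:
                if not blocked[i]:
                    return out_vessels[i]
            return None

        d_mother = g.diameter_um[mother_j]
        if len(out_vessels) == 2 and d_mother >= self.ps.d_star_um:
            k1, k2 = out_vessels
            fqb = qmag[0] / (qmag[0] + qmag[1])
            fqe = pries_split_fraction(fqb, d_mother, g.diameter_um[k1],
                                       g.diameter_um[k2], h_d_mother, self.ps)
            first = 0 if rng.random() < fqe else 1
            for i in (first, 1 - first):
                if not blocked[i]:
                    return out_vessels[i]
            return None

        # bifurcation rule: largest pressure force (dp/L) * A
        forces = []
        for k in out_vessels:
            other = self._head_node(k, q)
            dp = p[node] - p[other]
            forces.append(dp / g.length_um[k] * self.area_um2[k])
        i = bifurcation_rule_choice(forces, rng, blocked)
        return None if i is None else out_vessels[i]

    # -- the two per-step operations ---------------------------------------

    def advance(self, state: RBCState, flow, dt, rng, tables: VesselTables,
                counts=None):
        """Move every cell by v_RBC dt, enforce jams and route at nodes.

        The flow field is frozen for the step.  Cells crossing a node are
        processed in order of arrival; a cell that cannot enter any
        admissible daughter waits at the exit of its vessel and its
        followers stack behind it at the minimum spacing.
        """
        g = self.graph
        q = flow.q_m3s
        if counts is None:
            counts = state._counts
        occupied = np.flatnonzero(counts)
        if len(occupied) == 0:
            return 0
        vfac = tables.velocity_factor(counts)
        h_d = tables.discharge_hematocrit(counts)
        v_rbc_all = np.abs(q) * self.inv_area_m2 * vfac * 1e6  # um/s

        lengths = g.length_um
        bad = v_rbc_all * dt >= lengths
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"time step too large: a cell would traverse vessel "
                f"{g.vessel_id[j]} ({lengths[j]:.1f} um) in one step "
                f"({v_rbc_all[j] * dt:.1f} um); reduce dt"
            )
        pending = []
        for j in occupied:
            v = v_rbc_all[j]
            if v == 0.0:
                continue
            state._rebase(j, 1 if q[j] >= 0 else -1)
            state._off[j] += v * dt
            over = state._t[j][-1] + state._off[j] - lengths[j]
            if over > 0.0:
                pending.append((over / v, j))
        # earliest arrivals (largest remaining overshoot time) first
        pending.sort(key=lambda c: -c[0])
        queue = [j for _, j in pending]

        n_ejected = 0
        while queue:
            j = queue.pop(0)
            t = state._t[j]
            if not t:
                continue
            over = t[-1] + state._off[j] - lengths[j]
            if over <= 0.0:
                continue
            v_src = v_rbc_all[j]
            node = self._head_node(j, q)
            if g.is_boundary[node]:
                t.pop()
                state._ids[j].pop()
                state._counts[j] -= 1
                state.n_ejected += 1
                self.ejections_by_node[node] = self.ejections_by_node.get(node, 0) + 1
                n_ejected += 1
            else:
                out_vessels = [k for k in self.incident[node]
                               if k != j and q[k] != 0.0 and self._tail_node(k, q) == node]
                target = None
                if out_vessels:
                    target = self._choose_daughter(
                        state, flow, j, node, out_vessels, float(h_d[j]), rng
                    )
                if target is None:
                    # wait at the exit; followers stack behind
                    self._cascade_clamp(state, j)
                    continue
                t.pop()
                rid = state._ids[j].pop()
                state._counts[j] -= 1
                v_tgt = v_rbc_all[target]  # frozen-field velocity for this step
                entry = min(over / v_src * v_tgt,
                            max(self._entry_clearance(state, target), 0.0))
                self._insert(state, target, entry, rid, q)
                self.routings_by_vessel[target] = \
                    self.routings_by_vessel.get(target, 0) + 1
                # dt validation in the runner precludes a second crossing of
                # the freshly entered vessel within this step
            # re-check the same vessel for a further crosser
            if state._t[j] and state._t[j][-1] + state._off[j] > lengths[j]:
                queue.insert(0, j)
        return n_ejected

    def inject(self, state: RBCState, flow, dt, h_in, rng, tables=None):
        """Insert cells at inflow boundaries at volume flux q * H_in.

        Runs after the advance of a step: a cell whose arrival time falls
        at fraction f of the step enters at position (1 - f) v_RBC dt, so
        several cells per step enter as a correctly spaced train.  A
        fractional accumulator per inlet carries any deficit forward, so
        blocked insertions are deferred (never dropped) and the long-run
        rate is exact.
        """
        if not 0.0 <= h_in < 1.0:
            raise ValueError("inflow hematocrit must lie in [0, 1)")
        if h_in == 0.0:
            return 0
        g = self.graph
        q = flow.q_m3s
        n_new = 0
        for j in self.boundary_vessels:
            if q[j] == 0.0 or not g.is_boundary[self._tail_node(j, q)]:
                continue
            rate = abs(q[j]) * 1e18 * h_in / self.v_rbc_um3  # cells/s (q in um^3/s)
            acc0 = self._inject_acc.get(j, 0.0)
            acc = acc0 + rate * dt
            if acc < 1.0:
                self._inject_acc[j] = acc
                continue
            if state._counts[j] and state._dirn[j] != (1 if q[j] >= 0 else -1):
                state._rebase(j, 1 if q[j] >= 0 else -1)
            if tables is not None:
                v_entry = abs(q[j]) * self.inv_area_m2[j] * 1e6 * \
                    tables.velocity_factor(state._counts)[j]
            else:
                v_entry = abs(q[j]) * self.inv_area_m2[j] * 1e6
            k = 0
            while acc >= 1.0:
                # arrival time of the k-th due cell within this step
                # (overdue deferred cells enter immediately, at the entrance)
                t_due = max((np.floor(acc0) + 1.0 + k - acc0) / rate, 0.0)
                pos = max(min((dt - t_due) * v_entry, g.length_um[j] * 0.5), 0.0)
                clearance = self._entry_clearance(state, j)
                if clearance < 0.0:
                    break  # deferred, not dropped
                pos = min(pos, clearance)
                self._insert(state, j, pos, state._take_id(), q)
                state.n_injected += 1
                n_new += 1
                acc -= 1.0
                k += 1
            self._inject_acc[j] = acc
        return n_new


def advance_rbcs(state, graph, flow, dt, variant, rng, tables=None,
                 transport: RBCTransport | None = None):
    """Functional wrapper over :meth:`RBCTransport.advance`."""
    if transport is None:
        transport = RBCTransport(graph, variant)
    if tables is None:
        tables = VesselTables(graph, variant)
    transport.advance(state, flow, dt, rng, tables)
    return state


def inject_inflow_rbcs(state, graph, flow, dt, h_in, rng,
                       transport: RBCTransport | None = None):
    """Functional wrapper over :meth:`RBCTransport.inject`."""
    if transport is None:
        transport = RBCTransport(graph)
    transport.inject(state, flow, dt, h_in, rng)
    return state
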