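"""Resistance laws, Fahraeus relations and the nodal pressure solve.

Blood in microvessels behaves as a two-phase suspension.  Its apparent
viscosity relative to plasma depends on vessel diameter D and discharge
hematocrit H_d (Fahraeus-Lindqvist effect), and the hematocrit inside a
vessel (tube hematocrit H_t) is lower than the hematocrit of the blood
flowing through it (H_d) because red cells travel faster than the bulk
flow (Fahraeus effect).  Both effects are described here with the
Pries-Secomb *in vitro* empirical parameterizations; the coefficient set is
isolated in :class:`ResistanceParams` so an alternative fit can be swapped
in without touching the solver.

The flow in each vessel obeys Poiseuille's law with an effective resistance

    q_ij = (p_i - p_j) / R^e_ij,      R^e_ij = (128 mu L / pi D^4) * eta_rel

and mass balance at every interior node yields a sparse symmetric positive
definite linear system for the nodal pressures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu


@dataclass(frozen=True)
class ResistanceParams:
    """Plasma viscosity and the empirical in-vitro viscosity coefficients.

    mu_plasma is not reported by typical network studies and defaults to
    1.2e-3 Pa s, a standard value for blood plasma at 37 C.
    """

    mu_plasma: float = 1.2e-3  # Pa s
    # eta_45(D) = c0 * exp(c1 * D) + c2 + c3 * exp(c4 * D**c5), D in um
    eta45_coeffs: tuple = (220.0, -1.3, 3.2, -2.44, -0.06, 0.645)
    href: float = 0.45  # reference discharge hematocrit of the eta_45 curve

    def __post_init__(self):
        if self.mu_plasma <= 0:
            raise ValueError("mu_plasma must be positive")


DEFAULT_PARAMS = ResistanceParams()


def plasma_resistance(length_m, diameter_m, mu=DEFAULT_PARAMS.mu_plasma):
    """Poiseuille resistance 128 mu L / (pi D^4) of a circular vessel, SI units."""
    length_m = np.asarray(length_m, dtype=float)
    diameter_m = np.asarray(diameter_m, dtype=float)
    if np.any(length_m <= 0) or np.any(diameter_m <= 0) or mu <= 0:
        raise ValueError("length, diameter and viscosity must be positive")
    return 128.0 * mu * length_m / (np.pi * diameter_m**4)


def _eta_vitro_45(d_um, params: ResistanceParams):
    c0, c1, c2, c3, c4, c5 = params.eta45_coeffs
    return c0 * np.exp(c1 * d_um) + c2 + c3 * np.exp(c4 * d_um**c5)


def _shape_exponent(d_um):
    # controls how eta_rel varies with hematocrit away from the 0.45 reference
    d12 = 1.0 / (1.0 + 1e-11 * d_um**12)
    return (0.8 + np.exp(-0.075 * d_um)) * (-1.0 + d12) + d12


def relative_apparent_viscosity(d_um, h_d, params: ResistanceParams = DEFAULT_PARAMS):
    """Relative apparent viscosity eta_rel(D, H_d) of blood in a tube.

    Empirical in-vitro law: equals 1 at H_d = 0, increases with hematocrit,
    and has its diameter minimum near D ~ 7 um (Fahraeus-Lindqvist effect).
    D in micrometres, H_d a fraction in [0, 1).
    """
    d_um = np.asarray(d_um, dtype=float)
    h_d = np.asarray(h_d, dtype=float)
    if np.any(d_um <= 0):
        raise ValueError("diameter must be positive")
    if np.any((h_d < 0) | (h_d >= 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1)")
    eta45 = _eta_vitro_45(d_um, params)
    c = _shape_exponent(d_um)
    num = (1.0 - h_d) ** c - 1.0
    den = (1.0 - params.href) ** c - 1.0
    return 1.0 + (eta45 - 1.0) * num / den


def effective_resistance(length_m, diameter_m, h_d, params: ResistanceParams = DEFAULT_PARAMS):
    """Plasma resistance scaled by the relative apparent viscosity.

    Callers running the passive-particle model variant must pass h_d = 0,
    which reduces this to the pure-plasma value exactly.
    """
    d_um = np.asarray(diameter_m, dtype=float) * 1e6
    return plasma_resistance(length_m, diameter_m, params.mu_plasma) * relative_apparent_viscosity(
        d_um, h_d, params
    )


def tube_from_discharge(d_um, h_d):
    """Tube hematocrit H_t from discharge hematocrit H_d (Fahraeus effect).

    Uses the empirical relation
    H_t/H_d = H_d + (1 - H_d) (1 + 1.7 e^{-0.415 D} - 0.6 e^{-0.011 D}),
    D in micrometres.  The ratio is clamped to <= 1: below D ~ 2.7 um the
    raw fit exceeds 1, which would be unphysical (red cells cannot be
    slower than the bulk flow on average in this model).
    """
    d_um = np.asarray(d_um, dtype=float)
    h_d = np.asarray(h_d, dtype=float)
    if np.any((h_d < 0) | (h_d > 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1]")
    ratio = h_d + (1.0 - h_d) * (
        1.0 + 1.7 * np.exp(-0.415 * d_um) - 0.6 * np.exp(-0.011 * d_um)
    )
    ratio = np.minimum(ratio, 1.0)
    return ratio * h_d


def discharge_from_tube(d_um, h_t, tol=1e-12):
    """Invert the Fahraeus relation by bisection (it has no closed inverse).

    The forward map H_d -> H_t is monotone on [0, 1] with fixed points at 0
    and 1, so a bracketed bisection to ``tol`` always converges.
    """
    d_um = np.asarray(d_um, dtype=float)
    h_t = np.asarray(h_t, dtype=float)
    if np.any((h_t < 0) | (h_t > 1)):
        raise ValueError("tube hematocrit must lie in [0, 1]")
    lo = np.zeros(np.broadcast(d_um, h_t).shape)
    hi = np.ones_like(lo)
    d_b = np.broadcast_to(d_um, lo.shape)
    h_b = np.broadcast_to(h_t, lo.shape)
    for _ in range(60):  # 2^-60 < 1e-18, comfortably below tol
        mid = 0.5 * (lo + hi)
        too_low = tube_from_discharge(d_b, mid) < h_b
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol:
            break
    out = 0.5 * (lo + hi)
    # exact at the fixed points
    out = np.where(h_b == 0.0, 0.0, out)
    out = np.where(h_b == 1.0, 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class FlowState:
    """Instantaneous solution of the nodal pressure system.

    ``q`` is signed with respect to the storage orientation
    (positive = node_from -> node_to); ``v = q / A`` is the bulk velocity.
    """

    pressures_pa: np.ndarray      # (n_nodes,)
    q_m3s: np.ndarray             # (m,)
    v_ms: np.ndarray              # (m,)
    resistance: np.ndarray        # (m,) Pa s / m^3

    def to_frame(self, graph, h_d=None, h_t=None):
        """Per-vessel table (`vessel_id,q,v,He_d,Ht,Re`); hematocrits are
        optional because a pure-plasma solve has none."""
        import pandas as pd

        n = len(self.q_m3s)
        return pd.DataFrame(
            {
                "vessel_id": graph.vessel_id,
                "q": self.q_m3s,
                "v": self.v_ms,
                "He_d": np.full(n, np.nan) if h_d is None else np.asarray(h_d),
                "Ht": np.full(n, np.nan) if h_t is None else np.asarray(h_t),
                "Re": self.resistance,
            }
        )


class PressureSolver:
    """Sparse SPD solve of the nodal mass-balance system.

    The sparsity pattern depends only on topology, so one instance can be
    reused across time steps with changing resistances.  Dirichlet
    (boundary-pressure) nodes are eliminated from the system; the reduced
    matrix is the weighted graph Laplacian restricted to interior nodes,
    which is symmetric positive definite whenever every connected component
    touches a boundary node.
    """

    def __init__(self, graph, boundary_pressures_pa=None):
        self.graph = graph
        n = graph.n_nodes
        self.dirichlet = graph.is_boundary.copy()
        if not self.dirichlet.any():
            raise ValueError("at least one boundary node with a pressure is required")
        if boundary_pressures_pa is None:
            from .units import mmhg_to_pa

            boundary_pressures_pa = np.where(
                self.dirichlet, mmhg_to_pa(graph.boundary_pressure_mmhg), 0.0
            )
        self.p_dirichlet = np.asarray(boundary_pressures_pa, dtype=float)

        self.interior = np.flatnonzero(~self.dirichlet)
        self.n_interior = len(self.interior)
        reduced = -np.ones(n, dtype=np.int64)
        reduced[self.interior] = np.arange(self.n_interior)
        self._reduced = reduced

        i = graph.node_from_idx
        j = graph.node_to_idx
        ri, rj = reduced[i], reduced[j]
        # interior-interior off-diagonal entries (twice, for symmetry)
        both = (ri >= 0) & (rj >= 0)
        rows = np.concatenate([ri[both], rj[both], ri[ri >= 0], rj[rj >= 0]])
        cols = np.concatenate([rj[both], ri[both], ri[ri >= 0], rj[rj >= 0]])
        self._edge_off = np.flatnonzero(both)
        self._edge_di = np.flatnonzero(ri >= 0)
        self._edge_dj = np.flatnonzero(rj >= 0)
        # CSC pattern is fixed by topology: precompute the coalescing map so
        # a solve only rebuilds the data vector
        order = np.lexsort((rows, cols))
        rs, cs = rows[order], cols[order]
        if len(rs):
            new_entry = np.concatenate([[True], (np.diff(rs) != 0) | (np.diff(cs) != 0)])
        else:
            new_entry = np.empty(0, dtype=bool)
        starts = np.flatnonzero(new_entry)
        self._coo_order = order
        self._reduce_starts = starts
        self._csc_indices = rs[starts].astype(np.int32)
        uniq_cols = cs[starts]
        self._csc_indptr = np.searchsorted(
            uniq_cols, np.arange(self.n_interior + 1)
        ).astype(np.int32)
        # boundary-adjacent edges feeding the right-hand side
        self._rhs_mi = (ri >= 0) & (rj < 0)
        self._rhs_mj = (rj >= 0) & (ri < 0)
        self._rhs_ri = ri[self._rhs_mi]
        self._rhs_rj = rj[self._rhs_mj]
        self._rhs_pi = self.p_dirichlet[j[self._rhs_mi]]
        self._rhs_pj = self.p_dirichlet[i[self._rhs_mj]]

    def solve(self, resistance) -> FlowState:
        g = self.graph
        resistance = np.asarray(resistance, dtype=float)
        if np.any(~np.isfinite(resistance)) or np.any(resistance <= 0):
            raise ValueError("all effective resistances must be finite and positive")
        cond = 1.0 / resistance

        data = np.concatenate(
            [
                -cond[self._edge_off],
                -cond[self._edge_off],
                cond[self._edge_di],
                cond[self._edge_dj],
            ]
        )
        csc_data = np.add.reduceat(data[self._coo_order], self._reduce_starts) \
            if len(self._reduce_starts) else np.empty(0)
        a = csc_matrix(
            (csc_data, self._csc_indices, self._csc_indptr),
            shape=(self.n_interior, self.n_interior),
        )
        # right-hand side: conductance-weighted Dirichlet neighbours
        rhs = np.zeros(self.n_interior)
        np.add.at(rhs, self._rhs_ri, cond[self._rhs_mi] * self._rhs_pi)
        np.add.at(rhs, self._rhs_rj, cond[self._rhs_mj] * self._rhs_pj)

        if self.n_interior:
            try:
                lu = splu(a)
            except RuntimeError as err:  # singular factorization
                raise GraphTopologyError(
                    "pressure system is singular; an interior component has no "
                    "path to a boundary node"
                ) from err
            p_int = lu.solve(rhs)
            if np.any(~np.isfinite(p_int)):
                raise GraphTopologyError(
                    "pressure solve produced non-finite values; check that every "
                    "component touches a boundary node"
                )
        else:
            p_int = np.empty(0)

        p = self.p_dirichlet.copy()
        p[self.interior] = p_int
        q = (p[g.node_from_idx] - p[g.node_to_idx]) * cond
        area = g.cross_section_um2() * 1e-12  # m^2
        v = q / area
        return FlowState(pressures_pa=p, q_m3s=q, v_ms=v, resistance=resistance)


class GraphTopologyError(RuntimeError):
    """The pressure system is singular for the given boundary conditions."""


def solve_pressures(graph, resistance, boundary_pressures_pa=None) -> FlowState:
    """One-shot nodal pressure solve (see :class:`PressureSolver`).

    Boundary pressures default to the graph's own boundary table (mmHg,
    converted to Pa).  Returns a :class:`FlowState` whose interior
    mass-balance residual is at machine-precision level relative to the
    largest boundary-adjacent flow.
    """
    return PressureSolver(graph, boundary_pressures_pa).solve(resistance)
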