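"""Couple the pressure solve and RBC transport through time.

One time step is quasi-static: (1) tube hematocrit from the cell
occupancy, (2) discharge hematocrit and effective resistances via the
Fahraeus/viscosity tables, (3) sparse pressure solve, (4) inflow
injection, (5) cell advance with jams and routing.  After a warm-up the
per-vessel *median* velocity/flow/hematocrit over an averaging interval is
the canonical time-averaged field all analyses consume.

The averaging interval follows a perfusion-coverage rule: it is the time
needed for a fraction ``c`` (default 0.9) of vessels to be completely
perfused at least ``m`` (default 10) times, computed from per-vessel
turnover times (length / speed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .hemodynamics import PressureSolver
from .transport import (
    ModelVariant,
    RBCState,
    RBCTransport,
    VesselTables,
    V_RBC_UM3,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    #: time step (s).  None resolves it per network at run start as
    #: ``dt_safety * min_j(L_j / v_RBC_j)`` — cells must not traverse a
    #: whole vessel in one step, and the binding vessel differs between
    #: networks (sub-millisecond values are typical for cortical networks)
    dt: float | None = None
    dt_safety: float = 0.6
    variant: ModelVariant = ModelVariant.WITH_RBCS
    h_in: float = 0.3                 # inflow discharge hematocrit
    seed: int = 0
    perfusion_multiplicity: int = 10  # m: turnovers per vessel in the interval
    vessel_coverage: float = 0.9      # c: fraction of vessels covered
    warmup_multiplier: float = 2.0    # w: warm-up = w * averaging interval
    ma_window: int = 100              # moving-average window, steps
    ma_stride: int = 50               # moving-average stride, steps
    v_rbc_um3: float = V_RBC_UM3
    mu_plasma: float = 1.2e-3
    max_steps: int = 500_000

    def __post_init__(self):
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.vessel_coverage <= 1:
            raise ValueError("vessel coverage must lie in (0, 1]")
        if self.perfusion_multiplicity < 1 or self.warmup_multiplier < 1:
            raise ValueError("perfusion multiplicity and warm-up multiplier must be >= 1")


def turnover_time(length_m, v_ms):
    """Time to perfuse a vessel once: L / |v| (s); +inf for stagnant vessels."""
    length_m = np.asarray(length_m, dtype=float)
    v = np.abs(np.asarray(v_ms, dtype=float))
    with np.errstate(divide="ignore"):
        return np.where(v > 0, length_m / np.where(v > 0, v, 1.0), np.inf)


def averaging_interval(turnovers_s, m=10, c=0.9):
    """m times the c-quantile of the finite turnover times.

    The inverted-CDF quantile makes this exactly the smallest horizon over
    which a fraction c of the perfused vessels completes at least m
    turnovers; stagnant (infinite-turnover) vessels are excluded.
    """
    t = np.asarray(turnovers_s, dtype=float)
    finite = t[np.isfinite(t)]
    if len(finite) == 0:
        raise ValueError("no vessel has a finite turnover time")
    return m * float(np.quantile(finite, c, method="inverted_cdf"))


def moving_average(series, window=100, stride=50):
    """Mean per trailing window, sampled every ``stride`` steps.

    Presentation smoothing only; returns (end_indices, means).  A series
    shorter than the window yields empty output with a warning.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < window:
        log.warning("series of length %d is shorter than window %d", len(series), window)
        return np.empty(0, dtype=int), np.empty(0)
    cums = np.concatenate([[0.0], np.cumsum(series)])
    ends = np.arange(window, len(series) + 1, stride)
    means = (cums[ends] - cums[ends - window]) / window
    return ends, means


@dataclass
class TimeAveragedField:
    """Per-vessel medians over the recording window.

    ``direction`` is the sign of the median flow relative to the storage
    orientation; analyses treat it as the dominant flow direction.
    """

    vessel_id: np.ndarray
    median_v_ms: np.ndarray     # signed bulk velocity
    median_q_m3s: np.ndarray    # signed flow
    median_ht: np.ndarray       # tube hematocrit
    mean_n_rbc: np.ndarray      # time-averaged cell count
    mean_flux_hz: np.ndarray    # cells per second through the vessel
    direction: np.ndarray       # sign of median flow
    n_samples: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "vessel_id": self.vessel_id,
                "median_v_ms": self.median_v_ms,
                "median_q_m3s": self.median_q_m3s,
                "median_ht": self.median_ht,
                "mean_n_rbc": self.mean_n_rbc,
                "mean_flux_hz": self.mean_flux_hz,
                "direction": self.direction,
            }
        )


@dataclass
class ResultsStore:
    """Append-only per-step record of the recording window (float32)."""

    t_s: np.ndarray            # (T,)
    v_ms: np.ndarray           # (T, m)
    q_m3s: np.ndarray          # (T, m)
    ht: np.ndarray             # (T, m)
    n_rbc: np.ndarray          # (T, m) int16
    vessel_id: np.ndarray

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("t_s", "v_ms", "q_m3s", "ht", "n_rbc", "vessel_id"):
                fh.create_dataset(name, data=getattr(self, name), compression="gzip")


@dataclass
class SimulationResult:
    field: TimeAveragedField
    store: ResultsStore
    final_state: RBCState
    final_flow: object
    averaging_interval_s: float
    warmup_steps: int
    record_steps: int
    max_mass_residual: float
    config: SimulationConfig


def _validate_dt(graph, v_rbc_um_per_s, dt):
    ds = np.abs(v_rbc_um_per_s) * dt
    bad = ds >= graph.length_um
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"time step too large: a cell would traverse vessel {graph.vessel_id[j]} "
            f"({graph.length_um[j]:.1f} um) in one step ({ds[j]:.1f} um); reduce dt"
        )


def run_simulation(graph, config: SimulationConfig, initial_state: RBCState | None = None,
                   warmup_intervals: float | None = None,
                   record_intervals: float = 1.0):
    """Run to statistical steady state and return the time-averaged field.

    The run is fully reproducible for a fixed config: a single RNG stream
    seeded from ``config.seed`` drives injection and routing in a fixed
    order.  ``initial_state`` (e.g. the terminal state of a baseline run)
    replaces the default homogeneous-hematocrit initialization;
    ``warmup_intervals`` overrides the warm-up multiplier, which restarted
    runs use to re-warm for a single interval.
    """
    from .hemodynamics import ResistanceParams

    cfg = config
    variant = ModelVariant(cfg.variant)
    rng = np.random.default_rng(cfg.seed)
    params = ResistanceParams(mu_plasma=cfg.mu_plasma)
    tables = VesselTables(graph, variant, params, cfg.v_rbc_um3)
    transport = RBCTransport(graph, variant, v_rbc_um3=cfg.v_rbc_um3)
    solver = PressureSolver(graph)

    if initial_state is None:
        state = RBCState.from_uniform_hematocrit(graph, cfg.h_in, cfg.v_rbc_um3)
    else:
        state = initial_state.copy()

    area_m2 = graph.cross_section_um2() * 1e-12
    passive = variant == ModelVariant.PASSIVE_PARTICLES

    def solve(counts):
        return solver.solve(tables.resistance(counts))

    flow = solve(state.counts())
    static_flow = flow if passive else None

    def rbc_speed_um(flow, counts):
        return np.abs(flow.q_m3s) / area_m2 * tables.velocity_factor(counts) * 1e6

    if cfg.dt is None:
        v0 = rbc_speed_um(flow, state.counts())
        with np.errstate(divide="ignore"):
            limit = float(np.min(graph.length_um / np.where(v0 > 0, v0, 1e-30)))
        cfg = dc_replace(cfg, dt=cfg.dt_safety * limit)
        log.info("auto time step: %.3g s", cfg.dt)
    _validate_dt(graph, rbc_speed_um(flow, state.counts()), cfg.dt)

    m, c, w = cfg.perfusion_multiplicity, cfg.vessel_coverage, cfg.warmup_multiplier
    interval = averaging_interval(turnover_time(graph.length_um * 1e-6, flow.v_ms), m, c)
    w_eff = w if warmup_intervals is None else warmup_intervals
    warmup_steps = int(np.ceil(w_eff * interval / cfg.dt))
    if warmup_steps > cfg.max_steps:
        raise ValueError("warm-up exceeds max_steps; network too stagnant for this config")

    max_residual = 0.0
    b_from = graph.is_boundary[graph.node_from_idx]
    b_to = graph.is_boundary[graph.node_to_idx]
    b_any = b_from | b_to

    def step(flow):
        nonlocal max_residual
        counts = state._counts
        if static_flow is None:
            flow = solve(counts)
        # global mass balance: boundary inflow must equal boundary outflow
        net = float(np.sum(flow.q_m3s[b_from]) - np.sum(flow.q_m3s[b_to]))
        scale = float(np.max(np.abs(flow.q_m3s[b_any]), initial=0.0)) or 1.0
        max_residual = max(max_residual, abs(net) / scale)
        # advance first, then inject: cells due at fraction f of the step
        # enter at (1 - f) v dt, which a pre-advance insertion cannot express
        transport.advance(state, flow, cfg.dt, rng, tables, counts=None)
        transport.inject(state, flow, cfg.dt, cfg.h_in, rng, tables)
        return flow

    log.info("warm-up: %d steps (interval %.3g s)", warmup_steps, interval)
    for k in range(warmup_steps):
        flow = step(flow)
        if k % 1000 == 0:
            log.debug("warmup step %d, %d cells", k, state.n_rbcs)

    # recompute the interval from the warmed flow field
    interval = averaging_interval(turnover_time(graph.length_um * 1e-6, flow.v_ms), m, c)
    record_steps = max(int(np.ceil(record_intervals * interval / cfg.dt)), 10)
    if warmup_steps + record_steps > cfg.max_steps:
        raise ValueError("recording window exceeds max_steps")

    mv = np.empty((record_steps, graph.n_vessels), dtype=np.float32)
    mq = np.empty_like(mv)
    mh = np.empty_like(mv)
    mn = np.empty((record_steps, graph.n_vessels), dtype=np.int16)
    log.info("recording: %d steps (interval %.3g s)", record_steps, interval)
    for k in range(record_steps):
        flow = step(flow)
        counts = state.counts()
        mv[k] = flow.v_ms
        mq[k] = flow.q_m3s
        mh[k] = tables.tube_hematocrit(counts)
        mn[k] = counts
        if k % 1000 == 0:
            log.debug("record step %d, %d cells", k, state.n_rbcs)

    median_v = np.median(mv, axis=0).astype(float)
    median_q = np.median(mq, axis=0).astype(float)
    median_ht = np.median(mh, axis=0).astype(float)
    mean_n = mn.mean(axis=0).astype(float)
    # flux estimate: mean count turned over at the cell speed of the median flow
    vfac = tables.velocity_factor(np.round(mean_n).astype(np.int64))
    with np.errstate(divide="ignore", invalid="ignore"):
        flux = mean_n * np.abs(median_v) * vfac / (graph.length_um * 1e-6)
    flux[~np.isfinite(flux)] = 0.0

    fieldv = TimeAveragedField(
        vessel_id=graph.vessel_id.copy(),
        median_v_ms=median_v,
        median_q_m3s=median_q,
        median_ht=median_ht,
        mean_n_rbc=mean_n,
        mean_flux_hz=flux,
        direction=np.sign(median_q),
        n_samples=record_steps,
    )
    store = ResultsStore(
        t_s=(np.arange(record_steps) + warmup_steps + 1) * cfg.dt,
        v_ms=mv,
        q_m3s=mq,
        ht=mh,
        n_rbc=mn,
        vessel_id=graph.vessel_id.copy(),
    )
    return SimulationResult(
        field=fieldv,
        store=store,
        final_state=state,
        final_flow=flow,
        averaging_interval_s=interval,
        warmup_steps=warmup_steps,
        record_steps=record_steps,
        max_mass_residual=max_residual,
        config=cfg,
    )
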