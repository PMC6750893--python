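"""Single-capillary dilation experiments.

The functional experiment: pick a divergent capillary bifurcation, dilate
the distal part of one daughter by a factor f_dil (default 1.1), re-run
the simulation, and quantify the relative change in flow and cell count in
the bifurcation's vessels and up to three generations up- and downstream.

The segment adjacent to the bifurcation keeps its baseline diameter over a
length of six cell lengths (6 l_RBC), because the routing rule at the
bifurcation depends on the daughter cross-sections and would otherwise be
perturbed directly.  The relative flow change is reported per 100 um of
dilated length,

    d_r q = (q_act - q_base)/q_base * 100 um / L_dilated,

while the relative change in cell count needs no length normalization.
The quotient of flow ratios a = (q_d1/q_mother)_act / (q_d1/q_mother)_base
measures how much the flow split at the bifurcation shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .bifurcations import BalanceClass, BifurcationKind
from .graph import VascularGraph, generations_up_downstream
from .runner import SimulationConfig, run_simulation
from .transport import ModelVariant, RBCState, V_RBC_UM3

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilationSpec:
    """One dilation scenario: which daughter of which bifurcation, how much."""

    node_id: int
    daughter_vessel_id: int
    f_dil: float = 1.1
    l_const_um: float = None  # type: ignore[assignment]  # 6 l_RBC, filled in

    def __post_init__(self):
        if self.f_dil <= 1.0:
            raise ValueError("dilation factor must exceed 1")

    def with_l_const(self, graph, v_rbc_um3=V_RBC_UM3) -> "DilationSpec":
        """Fill in the constant-segment length from the baseline daughter."""
        j = graph.vessel_index(self.daughter_vessel_id)
        area = float(graph.cross_section_um2()[j])
        l_rbc = v_rbc_um3 / area
        return dc_replace(self, l_const_um=6.0 * l_rbc)


def select_candidate_bifurcations(graph, field, records, target_class, k, rng,
                                  h_min=0.3, centre_fraction=0.6):
    """Sample k suitable divergent bifurcations for dilation.

    Filters: (1) divergent capillary bifurcation, (2) balance class equals
    ``target_class``, (3) the node lies within ``centre_fraction`` of the
    maximum node distance from the network centre (avoids boundary
    effects), (4) the mother's median tube hematocrit is at least
    ``h_min`` so enough cells are present.  If fewer than k candidates
    survive, all of them are returned with a warning.
    """
    target_class = BalanceClass(target_class)
    centre = graph.pos_um.mean(axis=0)
    dist = np.linalg.norm(graph.pos_um - centre, axis=1)
    max_dist = dist.max()
    ht_by_id = dict(zip(field.vessel_id, field.median_ht))

    candidates = []
    for r in records:
        if r.kind != BifurcationKind.DIVERGENT or r.balance != target_class:
            continue
        node = graph.node_index(r.node_id)
        if dist[node] >= centre_fraction * max_dist:
            continue
        mother = r.mother_vessels[0]
        if ht_by_id[mother] < h_min:
            continue
        candidates.append(r.node_id)
    if len(candidates) < k:
        log.warning("only %d of the requested %d candidate bifurcations found",
                    len(candidates), k)
        return list(candidates)
    pick = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(pick)]


def split_and_dilate(graph, spec: DilationSpec):
    """Replace the chosen daughter by a constant and a dilated segment.

    The proximal segment (adjacent to the bifurcation) keeps the baseline
    diameter over ``l_const_um``; the distal remainder is dilated by
    ``f_dil``.  Total length is preserved and every other vessel is
    untouched.  Returns the new graph and a mapping with the new vessel
    and node ids.
    """
    if spec.l_const_um is None:
        spec = spec.with_l_const(graph)
    j = graph.vessel_index(spec.daughter_vessel_id)
    L = float(graph.length_um[j])
    l_dilated = L - spec.l_const_um
    if l_dilated <= 0:
        raise ValueError(
            f"daughter vessel {spec.daughter_vessel_id} (length {L:.1f} um) is too "
            f"short for a constant segment of {spec.l_const_um:.1f} um"
        )
    bif_idx = graph.node_index(spec.node_id)
    i_from, i_to = graph.node_from_idx[j], graph.node_to_idx[j]
    if bif_idx == i_from:
        near, far = i_from, i_to
    elif bif_idx == i_to:
        near, far = i_to, i_from
    else:
        raise ValueError("daughter vessel is not incident to the bifurcation node")

    frac = spec.l_const_um / L
    new_pos = graph.pos_um[near] + frac * (graph.pos_um[far] - graph.pos_um[near])
    new_node_id = int(graph.node_id.max()) + 1
    vmax = int(graph.vessel_id.max())
    prox_id, dist_id = vmax + 1, vmax + 2

    keep = np.arange(graph.n_vessels) != j
    node_id = np.concatenate([graph.node_id, [new_node_id]])
    pos = np.vstack([graph.pos_um, new_pos])
    is_b = np.concatenate([graph.is_boundary, [False]])
    bp = np.concatenate([graph.boundary_pressure_mmhg, [np.nan]])

    d_base = float(graph.diameter_um[j])
    new_from = [int(graph.node_id[near]), new_node_id]
    new_to = [new_node_id, int(graph.node_id[far])]
    g = VascularGraph(
        node_id=node_id,
        pos_um=pos,
        is_boundary=is_b,
        boundary_pressure_mmhg=bp,
        vessel_id=np.concatenate([graph.vessel_id[keep], [prox_id, dist_id]]),
        node_from=np.concatenate([graph.node_from[keep], [new_from[0], new_from[1]]]),
        node_to=np.concatenate([graph.node_to[keep], [new_to[0], new_to[1]]]),
        length_um=np.concatenate([graph.length_um[keep], [spec.l_const_um, l_dilated]]),
        diameter_um=np.concatenate(
            [graph.diameter_um[keep], [d_base, d_base * spec.f_dil]]
        ),
        vtype=np.concatenate([graph.vtype[keep], ["capillary", "capillary"]]),
    ).validate()
    info = {
        "proximal_vessel_id": prox_id,
        "dilated_vessel_id": dist_id,
        "new_node_id": new_node_id,
        "l_dilated_um": l_dilated,
        "l_const_um": spec.l_const_um,
    }
    return g, info


def map_state_to_split_graph(state: RBCState, new_graph, old_graph, spec: DilationSpec,
                             info) -> RBCState:
    """Carry the terminal cell positions of a baseline run onto the split graph."""
    new_state = RBCState(new_graph, state.v_rbc_um3)
    new_state._next_id = state._next_id
    new_state.n_injected = state.n_injected
    new_state.n_ejected = state.n_ejected
    j_old = old_graph.vessel_index(spec.daughter_vessel_id)
    prox = new_graph.vessel_index(info["proximal_vessel_id"])
    dist = new_graph.vessel_index(info["dilated_vessel_id"])
    bif_idx = old_graph.node_index(spec.node_id)
    bif_at_from = old_graph.node_from_idx[j_old] == bif_idx
    l_const = info["l_const_um"]
    L_old = float(old_graph.length_um[j_old])

    for j in range(old_graph.n_vessels):
        vid = old_graph.vessel_id[j]
        if vid == spec.daughter_vessel_id:
            for s, rid in state.items_s(j):
                # arc length measured from the bifurcation end
                t = s if bif_at_from else L_old - s
                if t <= l_const:
                    seg, pos_t = prox, t
                else:
                    seg, pos_t = dist, t - l_const
                pos_t = min(max(pos_t, 0.0), float(new_graph.length_um[seg]))
                new_state._t[seg].append(pos_t)
                new_state._ids[seg].append(rid)
            continue
        k = new_graph.vessel_index(vid)
        pairs = state.items_s(j)
        new_state._t[k] = [s for s, _ in pairs]
        new_state._ids[k] = [r for _, r in pairs]
    # proximal/distal segments keep the bifurcation-outward coordinate; the
    # split vessels inherit the old orientation (node_from at the bifurcation)
    for seg in (prox, dist):
        order = np.argsort(new_state._t[seg], kind="stable")
        new_state._t[seg] = [new_state._t[seg][i] for i in order]
        new_state._ids[seg] = [new_state._ids[seg][i] for i in order]
    new_state._counts = np.array([len(t) for t in new_state._t], dtype=np.int64)
    return new_state


def relative_flow_change(q_base, q_act, l_dilated_um):
    """Relative flow change per 100 um of dilated length."""
    if q_base == 0:
        raise ValueError("relative flow change undefined for zero baseline flow")
    return (q_act - q_base) / q_base * (100.0 / l_dilated_um)


def relative_nrbc_change(n_base, n_act):
    """Relative change in the time-averaged cell count."""
    if n_base <= 0:
        raise ValueError("relative cell-count change undefined for zero baseline count")
    return (n_act - n_base) / n_base


def flow_ratio_quotient(q_d1_base, q_mother_base, q_d1_act, q_mother_act):
    """a = (q_d1/q_mother)_activation / (q_d1/q_mother)_baseline."""
    if 0 in (q_d1_base, q_mother_base, q_mother_act):
        raise ValueError("flow ratio quotient undefined for zero flows")
    return (q_d1_act / q_mother_act) / (q_d1_base / q_mother_base)


@dataclass
class DilationResult:
    spec: DilationSpec
    variant: ModelVariant
    info: dict
    a: float
    drq_mother: float
    drq_dilated: float
    drq_const: float
    drn_mother: float
    drn_dilated: float
    drn_const: float
    generations: dict     # signed generation -> list of (vessel_id, drq, drn)
    failed: bool = False


def _field_maps(field):
    q = dict(zip(field.vessel_id, field.median_q_m3s))
    n = dict(zip(field.vessel_id, field.mean_n_rbc))
    return q, n


def run_dilation_campaign(graph, baseline_config: SimulationConfig, specs,
                          variants=(ModelVariant.WITH_RBCS,),
                          baselines=None, n_generations=3):
    """Run every spec under every variant and collect the relative changes.

    ``baselines`` may carry pre-computed baseline SimulationResults per
    variant (they are expensive); missing ones are computed.  Activation
    runs restart from the baseline terminal cell state mapped onto the
    split graph and re-warm for one averaging interval before recording,
    keeping runs comparable.  A failed scenario is recorded and the
    campaign continues.
    """
    baselines = dict(baselines or {})
    results = []
    for variant in variants:
        variant = ModelVariant(variant)
        cfg = SimulationConfig(**{**baseline_config.__dict__, "variant": variant})
        if variant not in baselines:
            log.info("running %s baseline", variant.value)
            baselines[variant] = run_simulation(graph, cfg)
        base = baselines[variant]
        q_base, n_base = _field_maps(base.field)
        for spec in specs:
            spec_f = spec.with_l_const(graph, cfg.v_rbc_um3)
            try:
                new_graph, info = split_and_dilate(graph, spec_f)
                init = map_state_to_split_graph(base.final_state, new_graph, graph,
                                                spec_f, info)
                act = run_simulation(new_graph, cfg, initial_state=init,
                                     warmup_intervals=1.0)
            except Exception:
                log.exception("dilation scenario %s failed", spec_f)
                results.append(DilationResult(spec_f, variant, {}, np.nan, *[np.nan] * 6,
                                              generations={}, failed=True))
                continue
            q_act, n_act = _field_maps(act.field)
            l_dil = info["l_dilated_um"]
            mother = spec_f_mother(graph, base.field, spec_f)
            const = spec_f_const_daughter(graph, base.field, spec_f)
            dil_old = spec_f.daughter_vessel_id
            dist_id = info["dilated_vessel_id"]
            prox_id = info["proximal_vessel_id"]

            q_dil_act = q_act[dist_id]
            n_dil_act = n_act[dist_id] + n_act[prox_id]

            gen_sets = generations_up_downstream(graph, base.field, spec_f.node_id,
                                                 n_generations)
            gens = {}
            for g, vset in gen_sets.items():
                rows = []
                for vid in sorted(vset):
                    qb, qa = q_base[vid], q_act.get(vid, np.nan)
                    nb, na = n_base[vid], n_act.get(vid, np.nan)
                    drq = relative_flow_change(qb, qa, l_dil) if qb != 0 else np.nan
                    drn = relative_nrbc_change(nb, na) if nb > 0 else np.nan
                    rows.append((vid, drq, drn))
                gens[g] = rows

            results.append(
                DilationResult(
                    spec=spec_f,
                    variant=variant,
                    info=info,
                    a=flow_ratio_quotient(q_base[dil_old], q_base[mother],
                                          q_dil_act, q_act[mother]),
                    drq_mother=relative_flow_change(q_base[mother], q_act[mother], l_dil),
                    drq_dilated=relative_flow_change(q_base[dil_old], q_dil_act, l_dil),
                    drq_const=relative_flow_change(q_base[const], q_act[const], l_dil),
                    drn_mother=relative_nrbc_change(n_base[mother], n_act[mother]),
                    drn_dilated=relative_nrbc_change(n_base[dil_old], n_dil_act),
                    drn_const=relative_nrbc_change(n_base[const], n_act[const]),
                    generations=gens,
                )
            )
    return results, baselines


def spec_f_mother(graph, field, spec: DilationSpec) -> int:
    """Vessel id of the mother vessel at the spec's bifurcation."""
    node = graph.node_index(spec.node_id)
    for j in graph.incident_vessels()[node]:
        d = field.direction[j]
        head = graph.node_to_idx[j] if d > 0 else graph.node_from_idx[j]
        if d != 0 and head == node:
            return int(graph.vessel_id[j])
    raise ValueError(f"no inflow vessel at node {spec.node_id}")


def spec_f_const_daughter(graph, field, spec: DilationSpec) -> int:
    """Vessel id of the un-dilated daughter at the spec's bifurcation."""
    node = graph.node_index(spec.node_id)
    for j in graph.incident_vessels()[node]:
        d = field.direction[j]
        tail = graph.node_from_idx[j] if d > 0 else graph.node_to_idx[j]
        if d != 0 and tail == node and graph.vessel_id[j] != spec.daughter_vessel_id:
            return int(graph.vessel_id[j])
    raise ValueError(f"no second daughter at node {spec.node_id}")
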