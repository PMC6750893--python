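"""Classification and balance statistics of capillary bifurcations.

A capillary bifurcation is a degree-3 node whose three incident vessels
are all capillaries.  Judged on the time-averaged flow field it is
*divergent* (one inflow, two outflows) or *convergent* (two inflows, one
outflow).  The relative velocity difference between the two outflow
(divergent) or inflow (convergent) vessels,

    |d_r v| = 2 |v_b1 - v_b2| / (v_b1 + v_b2),

lies in [0, 2]; bifurcations with |d_r v| <= 20% are called well-balanced
and those with |d_r v| > 40% unbalanced.  The degree of well-balanced
bifurcations (DoWB) is the fraction classified well-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

WELL_BALANCED_THRESHOLD = 0.20
UNBALANCED_THRESHOLD = 0.40


class BifurcationKind(str, Enum):
    DIVERGENT = "divergent"
    CONVERGENT = "convergent"


class BalanceClass(str, Enum):
    WELL_BALANCED = "well_balanced"
    INTERMEDIATE = "intermediate"
    UNBALANCED = "unbalanced"


def relative_velocity_difference(v1, v2):
    """2 |v1 - v2| / (v1 + v2) on velocity magnitudes; in [0, 2]."""
    v1, v2 = abs(float(v1)), abs(float(v2))
    if v1 + v2 == 0.0:
        raise ValueError("relative velocity difference undefined: both velocities zero")
    return 2.0 * abs(v1 - v2) / (v1 + v2)


def balance_class(drv, t_wb=WELL_BALANCED_THRESHOLD, t_ub=UNBALANCED_THRESHOLD):
    """Partition [0, 2] into well-balanced (<= t_wb), intermediate, unbalanced (> t_ub)."""
    if not 0 < t_wb < t_ub:
        raise ValueError("thresholds must satisfy 0 < t_wb < t_ub")
    if drv <= t_wb:
        return BalanceClass.WELL_BALANCED
    if drv > t_ub:
        return BalanceClass.UNBALANCED
    return BalanceClass.INTERMEDIATE


@dataclass
class BifurcationRecord:
    node_id: int
    kind: BifurcationKind
    mother_vessels: tuple        # vessel ids carrying flow into the node
    daughter_vessels: tuple      # vessel ids carrying flow out of the node
    v_b1: float                  # m/s, magnitude
    v_b2: float
    drv: float
    balance: BalanceClass


@dataclass
class BifurcationSet:
    records: list
    n_excluded_zero_flow: int
    n_excluded_high_degree: int

    @property
    def divergent(self):
        return [r for r in self.records if r.kind == BifurcationKind.DIVERGENT]

    @property
    def convergent(self):
        return [r for r in self.records if r.kind == BifurcationKind.CONVERGENT]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": [r.node_id for r in self.records],
                "kind": [r.kind.value for r in self.records],
                "v_b1_ms": [r.v_b1 for r in self.records],
                "v_b2_ms": [r.v_b2 for r in self.records],
                "drv": [r.drv for r in self.records],
                "balance": [r.balance.value for r in self.records],
            }
        )


def classify_bifurcations(graph, field, t_wb=WELL_BALANCED_THRESHOLD,
                          t_ub=UNBALANCED_THRESHOLD) -> BifurcationSet:
    """All capillary degree-3 nodes, classified on the time-averaged field.

    Interior nodes of degree other than 3 never enter the analysis (nodes
    above degree 3 are legal in the graph but are not bifurcations); a
    degree-3 capillary node with a zero-median-flow incident vessel is
    excluded and counted.
    """
    direction = field.direction
    v = np.abs(field.median_v_ms)
    inc = graph.incident_vessels()
    is_cap = graph.vtype.astype(str) == "capillary"

    records = []
    n_zero = 0
    n_high = 0
    for node in range(graph.n_nodes):
        if graph.is_boundary[node]:
            continue
        vs = inc[node]
        if len(vs) != 3:
            if len(vs) > 3 and all(is_cap[j] for j in vs):
                n_high += 1
            continue
        if not all(is_cap[j] for j in vs):
            continue
        if any(direction[j] == 0 for j in vs):
            n_zero += 1
            continue
        into = []
        outof = []
        for j in vs:
            head = graph.node_to_idx[j] if direction[j] > 0 else graph.node_from_idx[j]
            (into if head == node else outof).append(j)
        if len(outof) == 2:
            kind = BifurcationKind.DIVERGENT
            pair = outof
        elif len(into) == 2:
            kind = BifurcationKind.CONVERGENT
            pair = into
        else:  # all-in or all-out cannot happen with non-zero flows and mass balance
            n_zero += 1
            continue
        v1, v2 = float(v[pair[0]]), float(v[pair[1]])
        drv = relative_velocity_difference(v1, v2)
        records.append(
            BifurcationRecord(
                node_id=int(graph.node_id[node]),
                kind=kind,
                mother_vessels=tuple(int(graph.vessel_id[j]) for j in into),
                daughter_vessels=tuple(int(graph.vessel_id[j]) for j in outof),
                v_b1=v1,
                v_b2=v2,
                drv=drv,
                balance=balance_class(drv, t_wb, t_ub),
            )
        )
    return BifurcationSet(records, n_zero, n_high)


def degree_of_well_balanced(records, kind=BifurcationKind.DIVERGENT) -> float:
    """Fraction of bifurcations of the given kind classified well-balanced."""
    sel = [r for r in records if r.kind == kind]
    if not sel:
        raise ValueError(f"no {kind.value} bifurcations to summarize")
    wb = sum(1 for r in sel if r.balance == BalanceClass.WELL_BALANCED)
    return wb / len(sel)


def compare_distributions(sample_a, sample_b, mode="unpaired_one_sided",
                          alternative="less"):
    """Distribution comparison battery with a quartile/skewness summary.

    ``unpaired_one_sided``: one-sided Mann-Whitney U (default alternative:
    the median of ``sample_a`` is smaller); ``paired``: Wilcoxon
    signed-rank on aligned samples; ``ks_one_sided``: one-sided two-sample
    Kolmogorov-Smirnov.  Skewness is adjusted Fisher-Pearson.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    if mode == "unpaired_one_sided":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    elif mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired comparison requires aligned samples of equal length")
        diffs = a - b
        if np.all(diffs == 0):
            res = type("R", (), {"pvalue": 1.0, "statistic": 0.0})
        else:
            res = stats.wilcoxon(a, b, alternative=alternative)
    elif mode == "ks_one_sided":
        res = stats.ks_2samp(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    def summary(x):
        return {
            "q1": float(np.quantile(x, 0.25)),
            "median": float(np.median(x)),
            "q3": float(np.quantile(x, 0.75)),
            "skewness": float(stats.skew(x, bias=False)) if len(x) > 2 else float("nan"),
        }

    return {
        "a": summary(a),
        "b": summary(b),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mode": mode,
        "alternative": alternative,
    }


def read_measured_velocities(path, replicate=None) -> pd.DataFrame:
    """Ingest measured bifurcation velocity tables (mm/s in files).

    Expected columns: ``bifurcation_id,kind,vessel_role,replicate,velocity_mm_s``
    with ``vessel_role`` in {b1, b2} (daughters of a divergent bifurcation
    or mothers of a convergent one).  By default the median over the
    replicates of each vessel is used; passing ``replicate`` selects a
    single measurement instead.

    Returns one row per bifurcation with ``v_b1_ms``, ``v_b2_ms``, ``drv``.
    """
    df = pd.read_csv(path)
    required = {"bifurcation_id", "kind", "vessel_role", "replicate", "velocity_mm_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measured velocity table is missing columns {sorted(missing)}")
    if replicate is not None:
        df = df[df["replicate"] == replicate]
    per_vessel = (
        df.groupby(["bifurcation_id", "kind", "vessel_role"])["velocity_mm_s"]
        .median()
        .unstack("vessel_role")
    )
    out = per_vessel.reset_index()
    out["v_b1_ms"] = out["b1"].abs() * 1e-3
    out["v_b2_ms"] = out["b2"].abs() * 1e-3
    out["drv"] = [
        relative_velocity_difference(r.v_b1_ms, r.v_b2_ms) for r in out.itertuples()
    ]
    out["balance"] = [balance_class(d).value for d in out["drv"]]
    return out[["bifurcation_id", "kind", "v_b1_ms", "v_b2_ms", "drv", "balance"]]
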