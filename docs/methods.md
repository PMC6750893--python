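# Methods

`capflow` simulates blood flow in microvascular network graphs with
discrete red-blood-cell (RBC) tracking and provides the analyses built on
top of the time-averaged flow field: bifurcation velocity balancing,
single-capillary dilation experiments, and spatial statistics of
well-balanced bifurcations.  This note documents the model, its
assumptions, the numerical choices, and what the synthetic networks do and
do not emulate.

## The flow model

A network is a graph of nodes (bifurcations and in-/outflow endpoints)
connected by vessel segments with length `L`, diameter `D` and a type
label (pial arteriole, descending arteriole, capillary, ascending venule,
pial venule).  Flow in each vessel obeys Poiseuille's law with an
effective resistance,

    q_ij = (p_i - p_j) / R^e_ij,
    R^e_ij = (128 mu L_ij / (pi D_ij^4)) * eta_rel(D_ij, H_d),

where `mu` is the plasma viscosity (default 1.2e-3 Pa s, a standard value;
configurable) and `eta_rel` the relative apparent viscosity of blood.
Mass balance at every interior node plus fixed pressures at the boundary
nodes yields a sparse symmetric positive definite system, solved by sparse
LU factorization after eliminating the Dirichlet rows.  The sparsity
pattern and the coalescing map from edges to matrix entries are
precomputed once per topology, so a time step only rebuilds the data
vector and refactorizes.  Interior mass-balance residuals are at machine
precision (~1e-13 relative, checked against a dense full-matrix oracle).

Vessel orientation in storage is arbitrary; the sign of the flow relative
to the stored orientation defines the direction.  Files use micrometres
and mmHg; all internal computation is SI.

## Empirical blood rheology

Two empirical relations describe the two-phase character of blood, both
from the Pries in-vitro parameterization family; the coefficients sit in
one place (`ResistanceParams`, `PhaseSeparationParams`) so an alternative
fit can be swapped in.

*Fahraeus-Lindqvist effect* (viscosity law, `D` in um):

    eta_45(D)   = 220 e^{-1.3 D} + 3.2 - 2.44 e^{-0.06 D^0.645}
    C(D)        = (0.8 + e^{-0.075 D}) (-1 + 1/(1+1e-11 D^12)) + 1/(1+1e-11 D^12)
    eta_rel     = 1 + (eta_45 - 1) ((1-H_d)^C - 1) / ((1-0.45)^C - 1)

`eta_rel(D, 0) = 1` exactly, it increases with hematocrit, and its
diameter minimum lies near 7 um.  The argument is the *discharge*
hematocrit `H_d`.

*Fahraeus effect* (tube vs discharge hematocrit):

    H_t / H_d = H_d + (1 - H_d)(1 + 1.7 e^{-0.415 D} - 0.6 e^{-0.011 D})

Cells travel faster than the bulk flow, so the tube hematocrit `H_t`
inside a vessel is below the discharge hematocrit `H_d` of the blood
flowing through it.  Below `D ~ 2.7 um` the raw fit would put the ratio
above 1; it is clamped to <= 1 (the model's cells are never slower than
the bulk flow on average).  The relation has no closed inverse; `H_d(H_t)`
is obtained by bracketed bisection to 1e-12, and the forward/inverse pair
round-trips to better than 1e-10.

## Discrete RBC tracking

Each cell has a fixed volume `V_RBC` (default 49 um^3, a typical mouse
value; configurable) and occupies a length `l_RBC = V_RBC / A` in a vessel
of cross-section `A`.  Cells move at `v_RBC = v_bulk * H_d/H_t` and may
never come closer than `l_RBC` to their leader (traffic jams); a cell that
cannot enter any admissible downstream vessel waits at the exit and its
followers stack behind it at minimum spacing.

Routing at a divergent bifurcation depends on the mother diameter:

* `D >= 10 um`: the empirical logit law for the RBC flux fraction
  (`FQE` as a function of the bulk flow fraction `FQB`), with pure plasma
  skimming below `X0 = 0.4/D_mother` and full capture above `1 - X0`;
  applied stochastically per cell (a Bernoulli draw on `FQE`), which
  reproduces the law in expectation and is the natural discretization for
  tracked cells.
* `D < 10 um` (the whole capillary bed): the *bifurcation rule* — each
  cell enters the daughter exerting the larger pressure force
  `(dp/L) * A`.  Exact ties are broken by a fair coin; a blocked daughter
  yields to the other.  The `(dp/L) * A` form of the force follows the
  rule's qualitative statement (a function of the cross-section); it is
  isolated in one function.

Nodes with more than two outflow vessels (possible in the synthetic mesh)
generalize the same rules: pressure-force maximum for the full model, a
categorical draw on flow fractions otherwise.  Convergent nodes simply
merge in arrival order, later arrivals waiting if spacing forbids entry.

Inflow boundaries inject cells at volume flux `q * H_in` (inflow
discharge hematocrit `H_in = 0.3`).  Injection runs after the advance of
each step: a cell whose arrival falls at fraction `f` of the step enters
at position `(1 - f) v_RBC dt`, so several cells per step form a
correctly spaced train.  A per-inlet fractional accumulator carries
deficits forward, making the long-run rate exact even when the entrance
is temporarily blocked (verified against the analytic steady state of a
straight vessel to four decimals in `H_t`).

Model variants: `with_rbcs` (full model), `passive_particles` (cells
neither raise resistance nor phase-separate and move at bulk velocity) and
`no_phase_separation` (resistance and velocity effects kept, routing
proportional to flow).  The ledger `n(t) = n(0) + injected - ejected`
holds exactly over any horizon.

### Internal representation

Cell positions are stored per vessel in the travel coordinate (0 at the
flow entrance) minus a per-vessel offset; the uniform per-step motion is a
single vectorized offset update, and only node crossings, jams and
insertions touch individual cells.  Per-vessel lookup tables map the
(small, integer) cell count to `H_t`, `H_d`, `eta_rel`, effective
resistance and velocity factor, so one time step costs one table lookup,
one sparse solve and the event handling.

## Time stepping and averaging

One step is quasi-static: hematocrit from occupancy, resistances from the
tables, pressure solve, cell advance, injection.  The flow field is
frozen within a step; mid-step reversals are ignored.

The time step must keep every cell within one vessel per step.  Because
the binding vessel differs between networks, `dt` is resolved per network
at run start as `0.6 * min_j(L_j / v_RBC_j)` (sub-millisecond for the
networks here) and re-checked every step; an explicit error, never silent
subdivision, follows a violation.

The simulation warms up from a homogeneous hematocrit distribution for
`w = 2` averaging intervals, where one interval is the time for 90% of
the perfused vessels to complete at least 10 turnovers (turnover = length
/ speed; the inverted-CDF quantile makes this exactly the smallest
horizon with that coverage).  The interval is recomputed from the warmed
field before recording.  The canonical time-averaged field holds the
per-vessel *median* velocity, flow and tube hematocrit over one interval
(sampled every step), the mean cell count, and the dominant direction
(sign of median flow).  A moving average (window 100 steps, stride 50) is
available for presentation only.

All randomness — routing draws and tie-breaks — comes from one
`numpy` generator seeded from the config, in a fixed order; runs are
bit-reproducible.

## Bifurcation analysis

A capillary bifurcation is an interior degree-3 node whose three vessels
are all capillaries (higher-degree junctions are legal in the graph but
are not bifurcations).  On the time-averaged field it is divergent (one
inflow, two outflows) or convergent (two inflows, one outflow); a
zero-median-flow incident vessel excludes the node (counted).  The
relative velocity difference uses magnitudes of the median bulk velocity,

    |drv| = 2 |v_b1 - v_b2| / (v_b1 + v_b2)  in [0, 2],

over the daughters (divergent) or the mothers (convergent, unweighted).
Bifurcations with `|drv| <= 20%` are well-balanced (the boundary belongs
to the class), `> 40%` unbalanced.  DoWB is the well-balanced fraction.
Distribution comparisons use the one-sided Mann-Whitney U test (unpaired),
Wilcoxon signed-rank (paired) or the one-sided two-sample
Kolmogorov-Smirnov test, with Q1/median/Q3 and adjusted Fisher-Pearson
skewness summaries.  Measured velocity tables (mm/s, three replicates per
vessel) can be ingested; the per-vessel median, or one chosen replicate,
enters the same formula.  Simulated bulk velocities and measured cell
velocities are never mixed within one comparison.

## Dilation experiments

Candidate sites are divergent capillary bifurcations that are (1) of the
requested balance class on the baseline full-model field, (2) within 0.6
of the maximum node distance from the network centroid (boundary
avoidance), and (3) fed by a mother with median tube hematocrit >= 0.3.
From the survivors, `k` sites are drawn uniformly with the seeded
generator; if fewer survive, all are used (with a warning).

At a chosen site one daughter is split: the segment adjacent to the
bifurcation keeps the baseline diameter over `6 l_RBC` (so the
cross-section-dependent routing rule at the node is not perturbed
directly), and the distal remainder is dilated by `f_dil` (default 1.1).
The activation run restarts from the baseline terminal cell state mapped
onto the split graph and re-warms for one averaging interval before
recording — the baseline and activation runs stay maximally comparable.
Reported quantities:

    d_r q      = (q_act - q_base)/q_base * 100 um / L_dilated   (per vessel)
    d_r n_RBC  = (n_act - n_base)/n_base                        (per vessel)
    a          = (q_d1/q_mother)_act / (q_d1/q_mother)_base

plus the same changes pooled over vessels one to three generations up-
and downstream of the site (generation sets walk the flow-directed graph
outward from the site; a vessel reachable at two depths keeps the smaller
one, upstream winning ties; the site itself is generation 0 and
excluded).

## Spatial statistics

Depth (z, 0 at the pial surface) slices the cortex into five 200-um
analysis layers, half-open so a boundary depth belongs to the deeper
layer.  Distances to penetrating vessels use the main branch of each DA
and AV: the same-type path from the pial end with non-increasing diameter
(larger diameter on ties), sampled as a <= 1 um polyline for Euclidean
distances.  Flow-path lengths walk upstream (to the DA) or downstream (to
the AV), accumulating vessel lengths until the first target-type vessel,
by Dijkstra on the flow digraph.  The tissue grid divides the graph
bounding box into `gx x gy x gz` cubes and measures each centre's exact
point-to-segment distance to the nearest well-balanced outflow vessel;
the default 50 um influence radius is the mean inter-capillary distance.

## Synthetic networks

Real cortical reconstructions at this scale are not freely available, so
a seeded generator provides networks with the statistical structure the
analyses assume: a jittered cubic capillary mesh (spacing 50 um), thinned
from full 6-neighbour adjacency by random removal of non-bridge edges to
mean degree ~3 (never dropping a node below degree 2), which yields the
degree-3 capillary bifurcations the analyses run on while keeping the
mesh connected; vertical DA/AV trunks (15 um) at interior columns,
attached through one capillary offshoot per depth level, whose tops are
the only boundary nodes (60 mmHg at DA tops, 10 mmHg at AV tops —
plausible root pressures for penetrating cortical vessels); and capillary
diameters with a lognormal(median 4 um, geometric sd 1.2) marginal,
truncated below 10 um so the whole bed is governed by the bifurcation
rule.

Diameters are sampled from a spatially smoothed node field (three
neighbour-averaging sweeps) rather than independently per segment:
capillary calibres in real tissue vary smoothly, so sibling daughters
have similar cross-sections.  With independent draws the daughters differ
in area by ~1.7x on average, which alone forces `|drv| ~ 0.5` at
perfectly balanced flow and obscures every velocity-based analysis.

What the generator does *not* emulate: the depth-dependent topology of
real cortical networks (spatial-analysis results on synthetic lattices
are structural checks, not quantitative predictions), arteriolar/venular
trees on the pial surface, and the exact degree/length distributions of
reconstructed networks.  A median of 4-8 capillary segments between
arteriole and venule matches the cortical value of about six.

## Problem sizes and statistical power

The reference study runs on the seed-1 default lattice (7x7x7 mesh, ~570
vessels, ~100 capillary bifurcations) with ~12 s of simulated time per
run — sizes chosen so the whole test suite and the acceptance script
complete in minutes on one CPU.  Two consequences are worth stating
plainly:

* The direction of the velocity-balancing effect (lower divergent `|drv|`
  median and higher DoWB with RBCs than with passive particles)
  reproduces, but with only ~50 divergent bifurcations per group the
  one-sided Mann-Whitney comparison is underpowered: detecting a median
  shift of the size reported for real ~13,000-vessel networks at p < 0.05
  needs several hundred bifurcations per group.
* The dilation-site filters are deliberately selective (they pick
  concentrated, well-balanced, central bifurcations); on a network with a
  well-balanced pool of ~8, one to four sites survive, against 25 in a
  full-scale network with a pool of ~1,900.  Campaign statistics over so
  few sites carry wide uncertainty.  The reference campaign executes at
  most four scenarios per model variant, each scenario being a separate
  steady-state re-simulation.

## Known limitations

* Deviations from Poiseuille's law caused by cells lingering at
  bifurcation apexes are not modelled; cell-cell hydrodynamic
  interactions and deformation are outside scope.
* The in-vitro viscosity law underestimates in-vivo resistance (no
  endothelial surface layer); swapping the coefficient set changes the
  strength, not the direction, of the RBC effects.
* Vessels are straight segments between endpoints (no stored centerline
  curvature); tortuosity enters only through the length field.
* Packing allows tube hematocrit up to ~1 (`l_RBC = V_RBC/A`); real cells
  jam at lower tube hematocrit, so jam-mediated redistribution is, if
  anything, underrepresented.
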